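"""Compositional data machinery for nutrient balances.

Leaf and soil tests carry only relative information: concentrations live on
the simplex once closed to a measurement unit (e.g. 1000 g/kg). This module
provides closure, the filling value, sequential binary partitions (SBP),
the isometric log-ratio (ilr) transform and its inverse, the Aitchison
distance, and per-part perturbation ratios — everything the yield pipeline
needs to move between concentration space and orthonormal balance space.

A balance j over a partition with r_j parts in the numerator group and s_j
parts in the denominator group is

    ilr_j = sqrt(r_j * s_j / (r_j + s_j)) * ln( g(num) / g(den) )

with g the geometric mean. The bracket notation ``[den | num]`` used for
balance names puts the numerator group on the RIGHT-hand side, so e.g. the
leaf balance ``[B | Mg,Ca,K,N,P]`` increases when the macronutrients rise
relative to boron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Composition",
    "BalancePartition",
    "IlrTransformer",
    "close",
    "with_filling_value",
    "ilr",
    "ilr_inverse",
    "aitchison_distance",
    "perturbation_ratio",
    "leaf_partition",
    "soil_partition",
    "LEAF_PARTS",
    "SOIL_PARTS",
    "FILLING_VALUE_LABEL",
    "LEAF_KAPPA",
    "SOIL_KAPPA",
]

FILLING_VALUE_LABEL = "Fv"
#: leaf concentrations are closed to 1000 g/kg, soil Mehlich-3 to 1e6 mg/kg
LEAF_KAPPA = 1000.0
SOIL_KAPPA = 1.0e6

LEAF_PARTS = ("N", "P", "K", "Ca", "Mg", "B", "Al", FILLING_VALUE_LABEL)
SOIL_PARTS = ("P", "K", "Ca", "Mg", FILLING_VALUE_LABEL)


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


@dataclass(frozen=True)
class Composition:
    """An ordered vector of strictly positive parts closed to ``kappa``."""

    labels: tuple[str, ...]
    values: np.ndarray
    kappa: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != values.size:
            raise ValueError(
                f"{len(self.labels)} labels for {values.size} values"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("part labels must be unique")
        for lab, v in zip(self.labels, values):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"part {lab!r} is not strictly positive: {v}")
        if not np.isclose(values.sum(), self.kappa, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"values sum to {values.sum()} but kappa is {self.kappa}; "
                "use close() first"
            )

    @property
    def n_parts(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def reclose(self, kappa: float) -> "Composition":
        return close(self.values, kappa, labels=self.labels)


def close(values, kappa: float = 1.0, labels=None) -> Composition:
    """Rescale strictly positive amounts so they sum to ``kappa``."""
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(values.size))
    if kappa <= 0 or not np.isfinite(kappa):
        raise ValueError(f"closure constant must be positive, got {kappa}")
    for lab, v in zip(labels, values):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"part {lab!r} is not strictly positive: {v}")
    return Composition(tuple(labels), values * (kappa / values.sum()), kappa)


def with_filling_value(values, labels, kappa: float) -> Composition:
    """Append the filling value Fv = kappa - sum(measured parts).

    Measured tissue elements never exhaust the unit of measurement; the
    remainder (structural carbon, oxygen, ...) enters as a single part so
    the composition closes exactly to ``kappa``.
    """
    values = np.asarray(values, dtype=float)
    labels = tuple(labels)
    if FILLING_VALUE_LABEL in labels:
        raise ValueError(f"{FILLING_VALUE_LABEL!r} already present")
    for lab, v in zip(labels, values):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"part {lab!r} is not strictly positive: {v}")
    total = values.sum()
    if total >= kappa:
        raise ValueError(
            f"no room for filling value: parts sum to {total} >= kappa {kappa}"
        )
    return Composition(
        labels + (FILLING_VALUE_LABEL,),
        np.append(values, kappa - total),
        kappa,
    )


def multiplicative_replacement(
    table: np.ndarray, factor: float = 0.65
) -> tuple[np.ndarray, int]:
    """Replace nonpositive entries column-wise by ``factor`` x the smallest
    positive observed value of that column. Returns (table, n_replaced)."""
    table = np.array(table, dtype=float)
    n_replaced = 0
    for j in range(table.shape[1]):
        col = table[:, j]
        bad = ~(col > 0)
        if bad.any():
            positives = col[col > 0]
            if positives.size == 0:
                raise ValueError(f"column {j} has no positive values")
            col[bad] = factor * positives.min()
            n_replaced += int(bad.sum())
    return table, n_replaced


@dataclass(frozen=True)
class BalancePartition:
    """A sequential binary partition: D-1 ordered numerator/denominator
    splits of the part set, defining an orthonormal ilr basis."""

    labels: tuple[str, ...]
    #: sign matrix, shape (D-1, D); +1 numerator, -1 denominator, 0 inactive
    signs: np.ndarray
    #: display order of (numerator, denominator) labels per contrast
    contrast_order: tuple | None = None

    def __post_init__(self) -> None:
        signs = np.asarray(self.signs, dtype=int)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "labels", tuple(self.labels))
        d = len(self.labels)
        if signs.shape != (d - 1, d):
            raise ValueError(
                f"expected {d - 1} contrasts over {d} parts, got {signs.shape}"
            )
        if not np.isin(signs, (-1, 0, 1)).all():
            raise ValueError("sign entries must be -1, 0 or +1")
        # each contrast must split a previously unsplit group
        groups = [frozenset(range(d))]
        for j, row in enumerate(signs):
            active = frozenset(np.flatnonzero(row != 0))
            num = frozenset(np.flatnonzero(row > 0))
            den = frozenset(np.flatnonzero(row < 0))
            if not num or not den:
                raise ValueError(f"contrast {j} needs parts on both sides")
            if active not in groups:
                raise ValueError(
                    f"contrast {j} does not split an unsplit group: "
                    f"{sorted(self.labels[i] for i in active)}"
                )
            groups.remove(active)
            if len(num) > 1:
                groups.append(num)
            if len(den) > 1:
                groups.append(den)
        if groups:
            raise ValueError("partition leaves groups unsplit")

    @property
    def n_parts(self) -> int:
        return len(self.labels)

    @property
    def n_balances(self) -> int:
        return len(self.labels) - 1

    def contrast_matrix(self) -> np.ndarray:
        """Orthonormal Psi, shape (D-1, D): rows satisfy Psi @ Psi.T = I."""
        signs = self.signs
        r = (signs > 0).sum(axis=1).astype(float)
        s = (signs < 0).sum(axis=1).astype(float)
        psi = np.zeros_like(signs, dtype=float)
        for j in range(signs.shape[0]):
            psi[j, signs[j] > 0] = np.sqrt(s[j] / (r[j] * (r[j] + s[j])))
            psi[j, signs[j] < 0] = -np.sqrt(r[j] / (s[j] * (r[j] + s[j])))
        return psi

    def balance_names(self) -> list[str]:
        """Bracket names ``[den | num]`` (numerator group on the right),
        groups listed in the order the contrasts were defined."""
        names = []
        for j, row in enumerate(self.signs):
            if self.contrast_order is not None:
                num, den = self.contrast_order[j]
            else:
                num = [self.labels[i] for i in np.flatnonzero(row > 0)]
                den = [self.labels[i] for i in np.flatnonzero(row < 0)]
            names.append(f"[{','.join(den)} | {','.join(num)}]")
        return names

    def to_json(self) -> str:
        contrasts = []
        for j, row in enumerate(self.signs):
            if self.contrast_order is not None:
                num, den = self.contrast_order[j]
            else:
                num = [self.labels[i] for i in np.flatnonzero(row > 0)]
                den = [self.labels[i] for i in np.flatnonzero(row < 0)]
            contrasts.append({"num": list(num), "den": list(den)})
        return json.dumps(contrasts)

    @classmethod
    def from_json(cls, text: str, labels=None) -> "BalancePartition":
        contrasts = json.loads(text)
        if labels is None:
            seen: list[str] = []
            for c in contrasts:
                for lab in c["num"] + c["den"]:
                    if lab not in seen:
                        seen.append(lab)
            labels = seen
        labels = tuple(labels)
        signs = np.zeros((len(contrasts), len(labels)), dtype=int)
        for j, c in enumerate(contrasts):
            for lab in c["num"]:
                signs[j, labels.index(lab)] = 1
            for lab in c["den"]:
                signs[j, labels.index(lab)] = -1
        order = tuple((tuple(c["num"]), tuple(c["den"])) for c in contrasts)
        return cls(labels, signs, order)

    @classmethod
    def from_contrasts(cls, labels, contrasts) -> "BalancePartition":
        """Build from ``[(num_labels, den_labels), ...]`` pairs."""
        labels = tuple(labels)
        signs = np.zeros((len(contrasts), len(labels)), dtype=int)
        for j, (num, den) in enumerate(contrasts):
            for lab in num:
                signs[j, labels.index(lab)] = 1
            for lab in den:
                signs[j, labels.index(lab)] = -1
        order = tuple((tuple(num), tuple(den)) for num, den in contrasts)
        return cls(labels, signs, order)


def _check_labels(comp_labels, partition: BalancePartition) -> None:
    if tuple(comp_labels) != partition.labels:
        missing = set(partition.labels) - set(comp_labels)
        extra = set(comp_labels) - set(partition.labels)
        raise ValueError(
            "composition labels do not match partition: "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            if missing or extra
            else "composition labels are ordered differently than the partition"
        )


def ilr(comp: Composition, partition: BalancePartition) -> np.ndarray:
    """Isometric log-ratio coordinates of a composition under an SBP.

    Scale invariant: the closure constant cancels in every log ratio.
    """
    _check_labels(comp.labels, partition)
    logx = np.log(comp.values)
    return partition.contrast_matrix() @ logx


def ilr_array(values: np.ndarray, partition: BalancePartition) -> np.ndarray:
    """Row-wise ilr of a (n, D) array of positive parts (closure-free)."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("all parts must be strictly positive")
    return np.log(values) @ partition.contrast_matrix().T


def ilr_inverse(
    coordinates: np.ndarray, partition: BalancePartition, kappa: float = 1.0
) -> Composition:
    """Map balance coordinates back to a composition closed to ``kappa``."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.size != partition.n_balances:
        raise ValueError(
            f"expected {partition.n_balances} coordinates, got {coordinates.size}"
        )
    logx = partition.contrast_matrix().T @ coordinates
    return close(np.exp(logx), kappa, labels=partition.labels)


def ilr_inverse_array(
    coordinates: np.ndarray, partition: BalancePartition, kappa: float = 1.0
) -> np.ndarray:
    """Row-wise inverse ilr of an (n, D-1) coordinate array, closed rows."""
    coordinates = np.atleast_2d(np.asarray(coordinates, dtype=float))
    raw = np.exp(coordinates @ partition.contrast_matrix())
    return raw * (kappa / raw.sum(axis=1, keepdims=True))


def aitchison_distance(x: Composition, y: Composition) -> float:
    """Euclidean distance between ilr (equivalently clr) representations.

    The nutrient-imbalance metric: zero iff the two compositions are
    proportional, invariant to the SBP chosen and to the closure constant.
    """
    if x.labels != y.labels:
        raise ValueError(f"label mismatch: {x.labels} vs {y.labels}")
    lx, ly = np.log(x.values), np.log(y.values)
    clr_x = lx - lx.mean()
    clr_y = ly - ly.mean()
    return float(np.linalg.norm(clr_x - clr_y))


def perturbation_ratio(observed: Composition, target: Composition) -> dict[str, float]:
    """Component-wise observed/target ratios after closure to a common unit.

    A ratio above 1 flags a part in relative excess, below 1 in relative
    shortage — the direction of the misbalance, part by part.
    """
    if observed.labels != target.labels:
        raise ValueError(
            f"label mismatch: {observed.labels} vs {target.labels}"
        )
    obs = observed.reclose(1.0).values
    tgt = target.reclose(1.0).values
    return dict(zip(observed.labels, (obs / tgt).tolist()))


def leaf_partition() -> BalancePartition:
    """The 8-part leaf SBP: N, P, K, Ca, Mg, B, Al and the filling value."""
    return BalancePartition.from_contrasts(
        LEAF_PARTS,
        [
            (["B", "Al", "Mg", "Ca", "K", "P", "N"], ["Fv"]),
            (["B", "Mg", "Ca", "K", "N", "P"], ["Al"]),
            (["Mg", "Ca", "K", "N", "P"], ["B"]),
            (["N", "P"], ["Mg", "Ca", "K"]),
            (["N"], ["P"]),
            (["K"], ["Mg", "Ca"]),
            (["Ca"], ["Mg"]),
        ],
    )


def soil_partition() -> BalancePartition:
    """The 5-part soil SBP over Mehlich-3 P, K, Ca, Mg and the filling value."""
    return BalancePartition.from_contrasts(
        SOIL_PARTS,
        [
            (["Mg", "Ca", "K", "P"], ["Fv"]),
            (["P"], ["Mg", "Ca", "K"]),
            (["K"], ["Mg", "Ca"]),
            (["Ca"], ["Mg"]),
        ],
    )


class IlrTransformer:
    """Scikit-learn style transformer mapping part tables to ilr balances.

    Parameters
    ----------
    partition : BalancePartition
        The sequential binary partition defining the basis.
    kappa : float
        Closure constant used when back-transforming coordinates.
    """

    def __init__(self, partition: BalancePartition, kappa: float = 1.0):
        self.partition = partition
        self.kappa = kappa

    def get_params(self, deep: bool = True) -> dict:
        return {"partition": self.partition, "kappa": self.kappa}

    def set_params(self, **params) -> "IlrTransformer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "IlrTransformer":
        self.n_features_in_ = self.partition.n_parts
        self.feature_names_out_ = self.partition.balance_names()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ilr_array(np.atleast_2d(X), self.partition)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def inverse_transform(self, coordinates: np.ndarray) -> np.ndarray:
        return ilr_inverse_array(coordinates, self.partition, self.kappa)
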