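"""Replicate-level dataset synthesis, normalization and splitting.

The experiment reports, per treatment, only the mean ± SE of each rooting
response over six replicates.  The surrogate models, however, were fitted to
replicate-level rows (216 = 36 treatments × 6 replicates, split 130 train /
86 test).  This module reconstructs a statistically equivalent replicate
dataset: each replicate is drawn as ``mean + Normal(0, SE·sqrt(n_reps))``
(the SE→SD conversion) and clamped to the response's physical domain.

Also provided: min–max normalization to [−1, 1] with exact inversion, the
random 130/86 splitter, and analytic benchmark surfaces with a known interior
maximum for end-to-end parameter-recovery tests of the model + optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .media import ION_ORDER, IonProfile, load_reference_table

__all__ = [
    "RESPONSES",
    "TreatmentRecord",
    "NormalizationSpec",
    "SplitSpec",
    "treatments_from_reference",
    "expand_replicates",
    "split",
    "benchmark_surface",
    "BenchmarkSurface",
]

#: Response label -> (fixture column prefix, (lower, upper) physical domain).
RESPONSES: dict[str, tuple[str, tuple[float, float]]] = {
    "RN": ("rn", (0.0, np.inf)),
    "RL": ("rl", (0.0, np.inf)),
    "R%": ("rpct", (0.0, 1.0)),
    "FW": ("fw", (0.0, np.inf)),
    "DW": ("dw", (0.0, np.inf)),
}

#: Replicates per treatment in the modeled experiment.
DEFAULT_N_REPS = 6


@dataclass(frozen=True)
class TreatmentRecord:
    """One treatment: ion profile plus mean ± SE for each response."""

    code: int
    ions: IonProfile
    means: dict[str, float]
    ses: dict[str, float]
    n_reps: int = DEFAULT_N_REPS

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"treatment {self.code}: n_reps must be >= 1")
        for label in self.means:
            if label not in RESPONSES:
                raise ValueError(f"treatment {self.code}: unknown response {label!r}")
            mean, se = self.means[label], self.ses.get(label, 0.0)
            lo, hi = RESPONSES[label][1]
            if not (lo <= mean <= hi):
                raise ValueError(f"treatment {self.code}: {label} mean {mean} outside domain")
            if se < 0:
                raise ValueError(f"treatment {self.code}: {label} SE must be >= 0")


def treatments_from_reference(
    table: pd.DataFrame | None = None, n_reps: int = DEFAULT_N_REPS
) -> list[TreatmentRecord]:
    """Build treatment records from the reference table (packaged by default)."""
    if table is None:
        table = load_reference_table()
    out = []
    for _, row in table.iterrows():
        ions = IonProfile(**{ion: float(row[f"{ion}_mm"]) for ion in ION_ORDER})
        means = {label: float(row[f"{prefix}_mean"]) for label, (prefix, _) in RESPONSES.items()}
        ses = {label: float(row[f"{prefix}_se"]) for label, (prefix, _) in RESPONSES.items()}
        out.append(TreatmentRecord(int(row["code"]), ions, means, ses, n_reps))
    return out


def expand_replicates(
    treatments: Sequence[TreatmentRecord], response: str, seed: int
) -> pd.DataFrame:
    """Draw replicate-level observations for one response.

    Returns one row per replicate with columns ``code, no3, nh4, k, ca, cl,
    response, value``.  Values are ``mean + Normal(0, SE·sqrt(n_reps))``,
    clamped to the response domain; deterministic given ``seed``.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r} (expected one of {list(RESPONSES)})")
    lo, hi = RESPONSES[response][1]
    rng = np.random.default_rng(seed)
    rows = []
    for t in treatments:
        if response not in t.means:
            raise ValueError(f"treatment {t.code} lacks response {response!r}")
        mean, se = t.means[response], t.ses[response]
        sd = se * np.sqrt(t.n_reps)
        values = np.clip(mean + sd * rng.standard_normal(t.n_reps), lo, hi)
        ion_values = dict(zip(ION_ORDER, t.ions.as_array()))
        for v in values:
            rows.append({"code": t.code, **ion_values, "response": response, "value": float(v)})
    return pd.DataFrame(rows)


@dataclass
class NormalizationSpec:
    """Per-column min/max mapping onto [−1, 1] (exactly invertible).

    Built from data with :meth:`fit`; columns are the five ions plus
    ``value``.  GA candidates may fall outside the fitted range, in which
    case they map outside [−1, 1] — that is intentional.
    """

    minima: dict[str, float]
    maxima: dict[str, float]

    @classmethod
    def fit(cls, df: pd.DataFrame, columns: Sequence[str]) -> "NormalizationSpec":
        minima, maxima = {}, {}
        for col in columns:
            lo, hi = float(df[col].min()), float(df[col].max())
            if hi <= lo:
                raise ValueError(f"column {col!r}: max ({hi}) must exceed min ({lo})")
            minima[col], maxima[col] = lo, hi
        return cls(minima, maxima)

    @property
    def columns(self) -> list[str]:
        return list(self.minima)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.columns:
            lo, hi = self.minima[col], self.maxima[col]
            out[col] = 2.0 * (df[col] - lo) / (hi - lo) - 1.0
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.columns:
            lo, hi = self.minima[col], self.maxima[col]
            out[col] = (df[col] + 1.0) / 2.0 * (hi - lo) + lo
        return out

    # array helpers for the model/optimizer hot paths -------------------
    def transform_ions(self, X: np.ndarray) -> np.ndarray:
        lo = np.array([self.minima[c] for c in ION_ORDER])
        hi = np.array([self.maxima[c] for c in ION_ORDER])
        return 2.0 * (np.asarray(X, dtype=float) - lo) / (hi - lo) - 1.0

    def transform_value(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.minima["value"], self.maxima["value"]
        return 2.0 * (np.asarray(y, dtype=float) - lo) / (hi - lo) - 1.0

    def inverse_value(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.minima["value"], self.maxima["value"]
        return (np.asarray(y, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo

    def to_dict(self) -> dict:
        return {"minima": self.minima, "maxima": self.maxima}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(dict(d["minima"]), dict(d["maxima"]))


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition sizes (130/86 for the 216-row dataset)."""

    n_train: int = 130
    n_test: int = 86
    seed: int = 0
    min_media_per_partition: int = 30

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("partition sizes must be >= 1")


def split(rows: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition replicate rows into train/test.

    Disjoint, exhaustive and reproducible given the seed.  Guards against
    degenerate splits: each partition must touch at least
    ``min_media_per_partition`` distinct media (resampled with a shifted
    seed if not, which essentially never triggers at 216/36).
    """
    n = len(rows)
    if spec.n_train + spec.n_test != n:
        raise ValueError(f"split sizes {spec.n_train}+{spec.n_test} != {n} rows")
    required = min(spec.min_media_per_partition, rows["code"].nunique())
    for attempt in range(100):
        rng = np.random.default_rng(spec.seed + attempt)
        perm = rng.permutation(n)
        train = rows.iloc[perm[: spec.n_train]]
        test = rows.iloc[perm[spec.n_train :]]
        if train["code"].nunique() >= required and test["code"].nunique() >= required:
            return train, test
    raise RuntimeError("could not produce a non-degenerate split in 100 attempts")


# ---------------------------------------------------------------------------
# Known-truth benchmark surfaces


@dataclass
class BenchmarkSurface:
    """Analytic response surface with a known interior maximum.

    ``func`` maps an (n, 5) ion array to responses; ``argmax``/``maximum``
    are exact.  ``treatments`` carries sampled treatment records (means on
    the surface, constant SE) ready for :func:`expand_replicates`.
    """

    kind: str
    func: Callable[[np.ndarray], np.ndarray]
    argmax: np.ndarray
    maximum: float
    bounds: np.ndarray  # (5, 2)
    treatments: list[TreatmentRecord] = field(default_factory=list)


def _ion_bounds_from_reference() -> np.ndarray:
    table = load_reference_table()
    return np.array(
        [[table[f"{ion}_mm"].min(), table[f"{ion}_mm"].max()] for ion in ION_ORDER]
    )


def benchmark_surface(
    kind: Literal["quadratic_bowl", "table6_like"] = "quadratic_bowl",
    params: dict | None = None,
    seed: int = 0,
) -> BenchmarkSurface:
    """Construct a smooth surface over the experimental ion box.

    ``quadratic_bowl``: separable concave quadratic, maximum at ``center``
    (default: box midpoint).  ``params`` keys: ``center`` (5,), ``curvature``
    (per-ion weights, default 1), ``peak`` (maximum value, default 1),
    ``active`` (boolean mask of ions the surface depends on), ``se``
    (per-treatment SE, default 0.02), ``n_treatments`` (default 36).

    ``table6_like``: quadratic with a low-K+, mid-nitrogen optimum and a
    response range resembling the observed rooting percentages.
    """
    params = dict(params or {})
    bounds = _ion_bounds_from_reference()
    widths = bounds[:, 1] - bounds[:, 0]

    if kind == "quadratic_bowl":
        center = np.asarray(params.get("center", bounds.mean(axis=1)), dtype=float)
        peak = float(params.get("peak", 1.0))
        curvature = np.asarray(params.get("curvature", np.ones(5)), dtype=float)
        active = np.asarray(params.get("active", np.ones(5, dtype=bool)))
    elif kind == "table6_like":
        # low K+, moderate N, mild Ca/Cl dependence; peak near the best
        # observed rooting percentage
        lo = bounds[:, 0]
        center = lo + widths * np.array([0.6, 0.8, 0.05, 0.45, 0.3])
        peak = float(params.get("peak", 0.95))
        curvature = np.array([0.3, 0.5, 2.0, 0.4, 0.3])
        active = np.ones(5, dtype=bool)
    else:
        raise ValueError(f"unknown surface kind {kind!r}")

    if np.any(center < bounds[:, 0]) or np.any(center > bounds[:, 1]):
        raise ValueError("surface argmax lies outside the sampled ion bounds")

    curvature = np.where(active, curvature, 0.0)

    def func(X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - center) / widths
        return peak - np.sum(curvature * Z**2, axis=1)

    se = float(params.get("se", 0.02))
    n_treatments = int(params.get("n_treatments", 36))
    rng = np.random.default_rng(seed)
    # Latin-hypercube-ish stratified sampling of the box so every ion spans
    # its range, plus the corners of the active subspace for coverage
    u = (rng.permuted(np.tile(np.arange(n_treatments), (5, 1)), axis=1).T + rng.random((n_treatments, 5))) / n_treatments
    X = bounds[:, 0] + u * widths
    values = func(X)

    treatments = []
    for i in range(n_treatments):
        ions = IonProfile.from_array(X[i])
        value = float(max(values[i], 0.0))
        treatments.append(
            TreatmentRecord(
                code=i + 1,
                ions=ions,
                means={"R%": min(value, 1.0)} if peak <= 1.0 else {"RN": value},
                ses={"R%": se} if peak <= 1.0 else {"RN": se},
            )
        )

    return BenchmarkSurface(
        kind=kind,
        func=func,
        argmax=center.copy(),
        maximum=peak,
        bounds=bounds,
        treatments=treatments,
    )


def write_replicates(df: pd.DataFrame, path: str | Path, partition: pd.Series | None = None) -> None:
    """Write a replicate dataset CSV, optionally with a partition column."""
    out = df.copy()
    if partition is not None:
        out["partition"] = partition
    out.to_csv(path, index=False)
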