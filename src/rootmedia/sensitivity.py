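"""Input-importance analysis: variable sensitivity error and ratio.

For each ion, the variable sensitivity error (VSE) measures how well the
surrogate performs when that input is unavailable; the variable sensitivity
ratio (VSR) divides it by the error of the full model with all inputs
present, so VSR ≈ 1 marks an irrelevant input and large VSR an important
one.  Ions are ranked by descending VSR (rank 1 = most important).

"Unavailable" is implemented, by default, by freezing the trained model and
pinning the ion's column at its dataset mean (``hold_at_mean``), then
scoring RMSE in normalized space on the full dataset (train + test).  A
``retrain`` mode — refit a reduced 4-input network with the column removed —
is also provided, but it is uninformative for this factorial design: the
five ions are exactly collinear (NO3- = K+ + NH4+ + 2·Ca2+ on the nitrate
media, with Cl- indicating the calcium-salt branch), so a retrained network
reconstructs any removed ion from the remaining four and every VSR collapses
to ≈ 1.  Only a probe that leaves the trained weights fixed can expose which
inputs the model actually leans on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import ann
from .media import ION_ORDER
from .modeling import DatasetBundle

__all__ = ["SensitivityReport", "vse", "vsr", "rank_ions", "sensitivity_report"]

VseMode = Literal["retrain", "hold_at_mean"]


@dataclass
class SensitivityReport:
    """Per-ion VSE/VSR and importance ranks for one response model."""

    response: str
    full_error: float
    vse: dict[str, float]
    vsr: dict[str, float]
    ranks: dict[str, int]
    tie_flag: bool
    error_metric: str = "rmse_normalized"
    n_rows: int = 0
    mode: str = "hold_at_mean"

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "error_metric": self.error_metric,
            "mode": self.mode,
            "n_rows": self.n_rows,
            "full_error": self.full_error,
            "vse": self.vse,
            "vsr": self.vsr,
            "ranks": self.ranks,
            "tie_flag": self.tie_flag,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def full_model_error(weights: ann.NetworkWeights, bundle: DatasetBundle) -> float:
    """Normalized-space RMSE of the full model over all rows (train + test)."""
    return ann.rmse(bundle.yn_all, ann.forward(weights, bundle.Xn_all))


def vse(
    weights: ann.NetworkWeights,
    bundle: DatasetBundle,
    ion: str,
    config: ann.TrainingConfig | None = None,
    mode: VseMode = "hold_at_mean",
) -> float:
    """Model error (normalized RMSE over all rows) with one ion unavailable."""
    if ion not in ION_ORDER:
        raise ValueError(f"unknown ion {ion!r} (expected one of {ION_ORDER})")
    col = ION_ORDER.index(ion)

    if mode == "retrain":
        keep = [j for j in range(len(ION_ORDER)) if j != col]
        config = config or ann.TrainingConfig()
        result = ann.train(bundle.Xn_train[:, keep], bundle.yn_train, config)
        pred = ann.forward(result.weights, bundle.Xn_all[:, keep])
    elif mode == "hold_at_mean":
        X = bundle.Xn_all.copy()
        X[:, col] = X[:, col].mean()
        pred = ann.forward(weights, X)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ann.rmse(bundle.yn_all, pred)


def vsr(vse_value: float, full_error: float) -> float:
    """Ratio of the reduced-model error to the full-model error."""
    if full_error <= 0:
        raise ValueError(f"full-model error must be > 0, got {full_error}")
    return vse_value / full_error


def rank_ions(vsr_values: dict[str, float]) -> tuple[dict[str, int], bool]:
    """Rank ions 1..5 by descending VSR.

    Ties are broken by the fixed ion order (NO3-, NH4+, K+, Ca2+, Cl-) and
    flagged.  Non-finite VSRs are rejected.
    """
    if set(vsr_values) != set(ION_ORDER):
        raise ValueError(f"expected VSR for exactly the ions {ION_ORDER}")
    values = [vsr_values[ion] for ion in ION_ORDER]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite VSR")
    order = sorted(range(len(ION_ORDER)), key=lambda j: (-values[j], j))
    ranks = {ION_ORDER[j]: pos + 1 for pos, j in enumerate(order)}
    tie_flag = len(set(values)) < len(values)
    return ranks, tie_flag


def sensitivity_report(
    weights: ann.NetworkWeights,
    bundle: DatasetBundle,
    config: ann.TrainingConfig | None = None,
    mode: VseMode = "hold_at_mean",
) -> SensitivityReport:
    """VSE/VSR for every ion against one trained response model."""
    full = full_model_error(weights, bundle)
    vse_values = {ion: vse(weights, bundle, ion, config, mode) for ion in ION_ORDER}
    vsr_values = {ion: vsr(v, full) for ion, v in vse_values.items()}
    ranks, tie_flag = rank_ions(vsr_values)
    return SensitivityReport(
        response=bundle.response,
        full_error=full,
        vse=vse_values,
        vsr=vsr_values,
        ranks=ranks,
        tie_flag=tie_flag,
        n_rows=len(bundle.yn_all),
        mode=mode,
    )


def report_table(reports: list[SensitivityReport]) -> pd.DataFrame:
    """Stack per-response reports into an ions × {VSR, rank} table."""
    rows = []
    for rep in reports:
        for ion in ION_ORDER:
            rows.append(
                {
                    "response": rep.response,
                    "ion": ion,
                    "vse": rep.vse[ion],
                    "vsr": rep.vsr[ion],
                    "rank": rep.ranks[ion],
                }
            )
    return pd.DataFrame(rows)
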