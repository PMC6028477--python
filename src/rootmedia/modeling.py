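"""Dataset assembly and per-response model fitting.

Glue between the replicate generator and the network trainer: expand one
response's treatments into replicate rows, normalize all columns to [−1, 1]
over the full dataset (normalization precedes the random split), partition
into train/test, and fit the surrogate.  The resulting bundle carries
everything the sensitivity analysis and the optimizer need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ann
from .media import ION_ORDER
from .synth import (
    NormalizationSpec,
    SplitSpec,
    TreatmentRecord,
    expand_replicates,
    treatments_from_reference,
)

__all__ = ["DatasetBundle", "prepare_dataset", "train_response_model"]


@dataclass
class DatasetBundle:
    """One response's replicate dataset, normalized and partitioned."""

    response: str
    rows: pd.DataFrame  # original scale, with 'partition' column
    norm: NormalizationSpec
    train_index: np.ndarray
    test_index: np.ndarray
    Xn_all: np.ndarray
    yn_all: np.ndarray

    @property
    def Xn_train(self) -> np.ndarray:
        return self.Xn_all[self.train_index]

    @property
    def yn_train(self) -> np.ndarray:
        return self.yn_all[self.train_index]

    @property
    def Xn_test(self) -> np.ndarray:
        return self.Xn_all[self.test_index]

    @property
    def yn_test(self) -> np.ndarray:
        return self.yn_all[self.test_index]


def prepare_dataset(
    response: str,
    treatments: list[TreatmentRecord] | None = None,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
) -> DatasetBundle:
    """Expand, normalize and split one response's dataset.

    With the packaged 36-treatment table and 6 replicates this yields 216
    rows split 130/86.  The replicate draw uses ``seed`` and the split uses
    ``seed + 1`` so the two sources of randomness stay independent.
    """
    if treatments is None:
        treatments = treatments_from_reference()
    rows = expand_replicates(treatments, response, seed=seed)
    if split_spec is None:
        split_spec = SplitSpec(n_train=130, n_test=86, seed=seed + 1)

    columns = list(ION_ORDER) + ["value"]
    norm = NormalizationSpec.fit(rows, columns)
    normalized = norm.transform(rows)
    Xn_all = normalized[list(ION_ORDER)].to_numpy()
    yn_all = normalized["value"].to_numpy()

    n = len(rows)
    if split_spec.n_train + split_spec.n_test != n:
        raise ValueError(f"split sizes must sum to {n}")
    rng = np.random.default_rng(split_spec.seed)
    required = min(split_spec.min_media_per_partition, rows["code"].nunique())
    for attempt in range(100):
        perm = np.random.default_rng(split_spec.seed + attempt).permutation(n)
        train_idx, test_idx = perm[: split_spec.n_train], perm[split_spec.n_train :]
        if (
            rows.iloc[train_idx]["code"].nunique() >= required
            and rows.iloc[test_idx]["code"].nunique() >= required
        ):
            break
    else:  # pragma: no cover - unreachable at 216/36
        raise RuntimeError("could not produce a non-degenerate split")

    rows = rows.copy()
    rows["partition"] = "test"
    rows.iloc[train_idx, rows.columns.get_loc("partition")] = "train"
    return DatasetBundle(response, rows, norm, train_idx, test_idx, Xn_all, yn_all)


def train_response_model(
    bundle: DatasetBundle, config: ann.TrainingConfig | None = None
) -> tuple[ann.ResponseModel, ann.FitReport]:
    """Fit the 5–8–1 network on a bundle's training partition."""
    config = config or ann.TrainingConfig()
    result = ann.train(bundle.Xn_train, bundle.yn_train, config)
    report = ann.fit_report(
        bundle.response,
        result.weights,
        bundle.norm,
        bundle.Xn_train,
        bundle.yn_train,
        bundle.Xn_test,
        bundle.yn_test,
        result.epochs,
        result.stop_reason,
    )
    model = ann.ResponseModel(bundle.response, result.weights, bundle.norm)
    return model, report
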