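"""Train one 5-8-1 surrogate per rooting response and report fit quality.

Each response gets its own tansig/linear network trained with
Levenberg-Marquardt on its 130-row training partition (MSE goal 0.01,
max 800 epochs).  Reports R², RMSE and signed mean bias on both partitions
(original units) next to the published test R² for orientation, and writes
the models, fit reports and observed-vs-predicted scatter data.
"""

from pathlib import Path

import pandas as pd

from rootmedia import ann
from rootmedia.modeling import prepare_dataset, train_response_model
from rootmedia.pipeline import export_scatter
from rootmedia.synth import RESPONSES

OUT = Path("results")
OUT.mkdir(exist_ok=True)

SEED = 0
PUBLISHED_TEST_R2 = {"RN": 0.88, "RL": 0.88, "R%": 0.98, "FW": 0.94, "DW": 0.87}

rows = []
for response, (slug, _) in RESPONSES.items():
    bundle = prepare_dataset(response, seed=SEED)
    model, fit = train_response_model(bundle, ann.TrainingConfig(seed=SEED + 2))
    model.save(OUT / f"model_{slug}.json")
    fit.save(OUT / f"fit_{slug}.json")
    for part in ("train", "test"):
        scatter = export_scatter(model, bundle.rows[bundle.rows.partition == part])
        scatter["table"].to_csv(OUT / f"scatter_{slug}_{part}.csv", index=False)
    rows.append(
        {
            "response": response,
            "train_r2": fit.train["r2"],
            "test_r2": fit.test["r2"],
            "published_test_r2": PUBLISHED_TEST_R2[response],
            "test_rmse": fit.test["rmse"],
            "test_mbe": fit.test["mbe"],
            "epochs": fit.epochs,
            "stop_reason": fit.stop_reason,
        }
    )

table = pd.DataFrame(rows)
table.to_csv(OUT / "fit_statistics.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
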