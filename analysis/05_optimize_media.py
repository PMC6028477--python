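"""Search the experimental ion box for response-maximizing media with the GA.

Each trained surrogate serves as the fitness function for a real-coded
genetic algorithm (population 50, 500 generations, roulette-wheel selection,
arithmetic crossover at 0.85, Gaussian mutation at 0.1, one elite) over the
box spanned by the 36 experimental media.  Writes the per-response optimal
ion profiles, predicted responses at the optimum and convergence
trajectories.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rootmedia import ann, ga
from rootmedia.media import ION_ORDER
from rootmedia.modeling import prepare_dataset, train_response_model
from rootmedia.synth import RESPONSES

OUT = Path("results")
OUT.mkdir(exist_ok=True)

SEED = 0
bounds = ga.SearchBounds.from_reference()

rows = []
for response, (slug, _) in RESPONSES.items():
    bundle = prepare_dataset(response, seed=SEED)
    model, _ = train_response_model(bundle, ann.TrainingConfig(seed=SEED + 2))
    result = ga.optimize(model.predict, bounds, ga.GAConfig(seed=SEED + 3))
    result.save(OUT / f"optimum_{slug}.json")
    pd.DataFrame(
        {"generation": np.arange(len(result.trajectory)), "best": result.trajectory}
    ).to_csv(OUT / f"trajectory_{slug}.csv", index=False)
    rows.append(
        {
            "response": response,
            **{f"{ion}_mm": round(getattr(result.best_ions, ion), 2) for ion in ION_ORDER},
            "predicted_optimum": round(result.predicted_response, 3),
        }
    )

table = pd.DataFrame(rows)
table.to_csv(OUT / "optimal_media.csv", index=False)
print(table.to_string(index=False))
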