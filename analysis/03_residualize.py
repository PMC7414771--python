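"""Remove age / gender / age-by-gender effects from regional thickness.

Each region gets the minimum-AIC linear model from the candidate set
{1, age, gender, age+gender, age*gender}; residuals replace raw thickness
for all network construction downstream.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from scnet import io as scio
from scnet.preprocess import residualize_all

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/residuals.csv"))
    ap.add_argument("--model-log", type=Path,
                    default=Path("results/model_selection.json"))
    args = ap.parse_args()

    cohort = scio.read_thickness_table(args.cohort)
    resid = residualize_all(cohort.thickness, cohort.table["age"],
                            cohort.table["gender"])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    resid.residuals.to_csv(args.out)
    args.model_log.write_text(json.dumps(
        {r: {"terms": list(m.terms), "aic": m.aic} for r, m in resid.models.items()},
        indent=2,
    ))

    chosen = Counter("+".join(m.terms) for m in resid.models.values())
    print(f"wrote residuals for {resid.residuals.shape[1]} regions to {args.out}")
    for model, k in chosen.most_common():
        print(f"  {model}: selected for {k} regions")
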