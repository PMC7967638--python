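"""Derive the prenatal risk score from the published adjusted odds ratios.

The multiple exact fit of the three selected factors cannot be rerun from
counts alone (it needs the unpublished joint covariate distribution), but
its six printed adjusted odds ratios are sufficient input for the weight
rule: 3 points at OR >= 10, 2 points at 5 <= OR < 10, 1 point below 5.

Finding: the rule reproduces the published score formula —
3 x unmarried + 2 x marital-status-not-answered +
1 x marital-status-not-investigated + 2 x abortion history +
1 x stopped smoking + 2 x smoking — with maximum attainable score 7.

Writes results/score_formula.json.
"""

import math
from pathlib import Path

from prenatal_risk.exact import ExactParameterInference
from prenatal_risk.score import WeightRule, compute_score, derive_weights

RESULTS = Path(__file__).resolve().parent.parent / "results"

# Published adjusted odds ratios of the multiple exact fit.
ADJUSTED_ORS = {
    "marital_status=unmarried": 12.14,
    "marital_status=not_answered": 8.76,
    "marital_status=not_investigated": 3.10,
    "abortion_history=yes": 5.82,
    "smoking=stopped": 3.35,
    "smoking=yes": 5.30,
}


def main() -> None:
    fits = [
        ExactParameterInference(
            parameter_name=name, estimate_kind="cmle", odds_ratio=orr,
            ci_lower=math.nan, ci_upper=math.nan, p_value=math.nan,
            t_observed=0, t_min=0, t_max=0,
        )
        for name, orr in ADJUSTED_ORS.items()
    ]
    formula = derive_weights(fits, rule=WeightRule())
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "score_formula.json"
    out.write_text(formula.to_json())
    for var, cat, w in formula.terms:
        print(f"  {w} x {var}={cat}  (adjusted OR {ADJUSTED_ORS[f'{var}={cat}']})")
    print(f"Maximum attainable score: {formula.max_score}")
    example = {"marital_status": "unmarried", "abortion_history": "yes",
               "smoking": "yes"}
    print(f"Example record {example} scores {compute_score(example, formula)}")
    print(f"Wrote {out}")


if __name__ == "__main__":
    main()
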