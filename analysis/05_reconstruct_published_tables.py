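"""Rebuild the published count tables and recompute every headline
metric from them.

This is the fixture-exact leg of the analysis: the integer 2x2 tables
recovered from the printed percentages and group sizes, with
sensitivity/specificity/PPV/NPV/accuracy/Youden/kappa and the three CI
constructions recomputed from counts alone.

Writes results/published/fixtures.json and recomputed_metrics.tsv.
"""

from pathlib import Path

import pandas as pd

from methpanel.core import as_percent
from methpanel.evaluation import ci_wald, ci_wilson, kappa, metrics
from methpanel.fixtures import build_fixtures
from methpanel.io import write_fixtures_json


def main(out_dir: Path = Path("results/published")) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = build_fixtures()
    write_fixtures_json(fx, out_dir / "fixtures.json")

    rows = []
    for name, c in fx.tables.items():
        rep = metrics(c)
        rows.append({
            "table": name, **c.as_dict(),
            "sensitivity_pct": as_percent(rep.sensitivity),
            "specificity_pct": as_percent(rep.specificity),
            "ppv_pct": as_percent(rep.ppv),
            "npv_pct": as_percent(rep.npv),
            "accuracy_pct": as_percent(rep.accuracy),
            "youden_j": round(rep.youden_j, 2),
            "kappa": round(rep.kappa, 2),
        })
    table = pd.DataFrame(rows).set_index("table")
    table.to_csv(out_dir / "recomputed_metrics.tsv", sep="\t")
    print(table.to_string())

    co = fx.tables["clinical_overall"]
    lo, hi = ci_wilson(co.tp, co.tp + co.fn)
    print(f"\noverall sensitivity {as_percent(co.tp / (co.tp + co.fn))}% "
          f"(Wilson 95% CI {as_percent(lo)}-{as_percent(hi)})")
    s0_tp, s0_n = fx.stage_counts["stage0"]
    lo, hi = ci_wald(s0_tp, s0_n)
    print(f"stage-0 sensitivity {as_percent(s0_tp / s0_n)}% "
          f"(Wald 95% CI {as_percent(lo)}-{as_percent(hi)})")

    stage = pd.DataFrame(
        [{"stage": s, "tp": tp, "n": n,
          "sensitivity_pct": as_percent(tp / n)}
         for s, (tp, n) in fx.stage_counts.items()]
    )
    print("\n" + stage.to_string(index=False))


if __name__ == "__main__":
    main()
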