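"""Run marker discovery on the simulated discovery matrix.

Screens every region against the three hypermethylation criteria
(adjusted P < 1e-2, tumor-minus-normal delta > 0.1, WBC mean < 0.1),
one-hot-transforms the plasma compartment at the control 95th
percentile, and selects a 6-region panel by regularised logistic
ranking. Reports how many planted regions the chain recovered.

Writes results/discovery/dmr_results.tsv and selected_markers.json.
"""

import json
import sys
from pathlib import Path

from methpanel.core import MethylMatrix
from methpanel.discovery import (
    dmr_table,
    onehot_transform,
    screen_dmrs,
    select_markers,
)
from methpanel.io import read_methyl_matrix


def main(
    in_dir: Path = Path("results/simulated/discovery"),
    out_dir: Path = Path("results/discovery"),
    k: int = 6,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = read_methyl_matrix(
        in_dir / "matrix.tsv", in_dir / "regions.bed", in_dir / "samples.csv"
    )
    planted = set((in_dir / "planted_regions.txt").read_text().split())

    results = screen_dmrs(matrix)
    table = dmr_table(results)
    table.to_csv(out_dir / "dmr_results.tsv", sep="\t", index=False,
                 float_format="%.6g")
    passing = [r.region.key for r in results if r.pass_overall]
    print(f"screen: {len(passing)} of {len(results)} regions pass "
          f"({len(set(passing) & planted)}/{len(planted)} planted recovered)")

    plasma_ids = [s for s in matrix.sample_ids
                  if matrix.groups[s].startswith("plasma")]
    plasma = MethylMatrix(
        regions=matrix.regions,
        values=matrix.values[plasma_ids],
        groups={s: matrix.groups[s] for s in plasma_ids},
    )
    controls = [s for s in plasma_ids if matrix.groups[s] == "plasma_control"]
    oh = onehot_transform(plasma, controls)
    labels = {s: ("case" if matrix.groups[s] == "plasma_case" else "control")
              for s in plasma_ids}
    k_eff = min(k, len(passing))
    model = select_markers(
        oh, labels, k=k_eff, candidate_regions=passing,
        p_adj={r.region.key: r.p_adj for r in results},
    )
    payload = {
        "selected_regions": model.selected_regions,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "n_planted_selected": len(set(model.selected_regions) & planted),
    }
    (out_dir / "selected_markers.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(f"selected {k_eff}-region panel, "
          f"{payload['n_planted_selected']} planted: "
          + ", ".join(model.selected_regions))


if __name__ == "__main__":
    main()
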