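"""Simulate the two synthetic datasets every later step consumes.

Writes under results/simulated/:
  discovery/  -- a 500-region methylation matrix (tumor, adjacent normal,
                 WBC, plasma compartments) with 10 planted
                 hypermethylated regions, plus the planted-region key
  cohort.csv  -- a 1,429-participant qMSP cohort at the clinical
                 cohort's group sizes and published per-stratum panel
                 positivity rates
"""

import sys
from pathlib import Path

from methpanel.io import write_methyl_matrix, write_qmsp_cohort
from methpanel.simulate import (
    CohortSpec,
    DiscoverySpec,
    generate_discovery_data,
    generate_qmsp_cohort,
)


def main(seed: int = 1, out_root: Path = Path("results/simulated")) -> None:
    disc_dir = out_root / "discovery"
    disc_dir.mkdir(parents=True, exist_ok=True)

    dspec = DiscoverySpec(seed=seed)
    matrix, planted = generate_discovery_data(dspec)
    write_methyl_matrix(
        matrix,
        disc_dir / "matrix.tsv",
        disc_dir / "regions.bed",
        disc_dir / "samples.csv",
    )
    (disc_dir / "planted_regions.txt").write_text("\n".join(planted) + "\n")
    print(f"discovery matrix: {len(matrix.regions)} regions x "
          f"{len(matrix.sample_ids)} samples, {len(planted)} planted DMRs")

    cspec = CohortSpec(seed=seed)
    records = generate_qmsp_cohort(cspec)
    write_qmsp_cohort(records, out_root / "cohort.csv")
    n_cases = sum(r.is_case for r in records)
    print(f"qMSP cohort: {len(records)} participants "
          f"({n_cases} EC cases) -> {out_root / 'cohort.csv'}")


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    main(seed)
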