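"""Generate the synthetic study cohort and write it to results/cohort/.

Produces the full fixture bundle the later drivers analyze: structured
genotypes with a planted causal locus, the ordinal killing phenotype,
virome PCR panels with ground-truth presence calls, KHS1-like ORF alleles
with planted premature stops, and a killer-by-lawn assay matrix.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, build_cohort  # noqa: E402

from killerome import io  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg, gm, labels, grm, y, panels, statuses, orfs, assays = build_cohort(args.seed)
    cohort = io.Cohort(
        panels=panels, assays=assays, statuses=statuses, genotypes=gm, orfs=orfs
    )
    paths = io.write_cohort(cohort, COHORT_DIR)
    pd.DataFrame({"strain_id": gm.strain_ids, "score": y}).to_csv(
        COHORT_DIR / "phenotype.tsv", sep="\t", index=False
    )
    pd.DataFrame({"strain_id": gm.strain_ids, "subpop": labels}).to_csv(
        COHORT_DIR / "subpops.tsv", sep="\t", index=False
    )

    n_la = sum(s.present for s in statuses if s.virus == "L-A")
    n_m = sum(s.present for s in statuses if s.virus in ("M1", "M2", "M28", "Mlus"))
    print(f"cohort of {gm.n_strains} strains x {gm.n_sites} sites written to {COHORT_DIR}")
    print(f"  L-A+ strains: {n_la}; M-satellite+ strains: {n_m} (all L-A+)")
    print(f"  causal locus: {gm.site_ids[cfg.causal_site_index]} (effect {cfg.causal_effect} latent SD)")
    print(f"  files: {', '.join(p.name for p in paths.values())}, phenotype.tsv, subpops.tsv")


if __name__ == "__main__":
    main()
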