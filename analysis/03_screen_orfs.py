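"""Screen the cohort's killer-gene ORFs and census the KHS1 classes.

Detects premature stop codons in every cohort ORF allele, tabulates the
allele categories, and reproduces the six-class KHS1 genotype-by-phenotype
census from the packaged per-strain table.
"""

import argparse
import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_or_build  # noqa: E402

from killerome import io  # noqa: E402
from killerome.datasets import load_khs1_cohort_synthetic  # noqa: E402
from killerome.killer import assign_khs1_class  # noqa: E402
from killerome.orfs import annotate_orf  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort, _ = load_or_build(args.seed)
    records = [annotate_orf(o) for o in cohort.orfs]
    allele_census = Counter(r.genotype_class.value for r in records)
    orf_report = pd.DataFrame(
        {
            "strain_id": [r.strain_id for r in records],
            "gene": [r.gene for r in records],
            "genotype_class": [r.genotype_class.value for r in records],
            "stops": [
                ";".join(f"{i}:{t.value}" for i, t in r.stops) for r in records
            ],
        }
    )

    khs1 = load_khs1_cohort_synthetic()
    labels = [
        assign_khs1_class(
            r.strain_id, r.khs1_genotype, bool(r.kills_cglabrata), bool(r.killed_by_reference)
        ).class_label
        for r in khs1.itertuples(index=False)
    ]
    class_census = Counter(labels)
    classes = pd.DataFrame(
        {"strain_id": khs1["strain_id"], "class_label": labels}
    )

    io.write_report({"orf_report": orf_report, "khs1_classes": classes}, RESULTS)
    print("cohort ORF allele census:", dict(sorted(allele_census.items())))
    print("KHS1 class census:", dict(sorted(class_census.items())))
    print(
        f"C. glabrata killers (classes 3+4): "
        f"{sum(v for k, v in class_census.items() if k.startswith(('3', '4')))}"
    )
    print(f"tables written to {RESULTS}/orf_report.tsv and khs1_classes.tsv")


if __name__ == "__main__":
    main()
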