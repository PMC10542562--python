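"""Type the cohort virome: presence calls, PCR genotype census, dependency audit.

Re-derives presence from the raw PCR panels (masked nuclear-cDNA signals
excluded), tabulates a per-virus summary alongside the published survey
design, audits helper-dependence and satellite-exclusion rules, and writes
the virome table under results/.
"""

import argparse
import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_or_build  # noqa: E402

from killerome import io  # noqa: E402
from killerome.datasets import load_pcr_summary  # noqa: E402
from killerome.virome import status_from_panel, validate_dependencies  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort, _ = load_or_build(args.seed)
    statuses = [status_from_panel(p) for p in cohort.panels]

    rows = []
    for virus in load_pcr_summary()["virus"]:
        calls = [s for s in statuses if s.virus == virus]
        genotypes = Counter(s.pcr_genotype for s in calls if s.present)
        rows.append(
            {
                "virus": virus,
                "n_present": sum(s.present for s in calls),
                "n_cdna_signal": sum(s.cdna_signal for s in calls),
                "n_pcr_genotypes": len(genotypes),
            }
        )
    summary = pd.DataFrame(rows)
    violations = validate_dependencies(statuses)

    io.write_report(
        {
            "virome_summary": summary,
            "virome_calls": pd.DataFrame(
                {
                    "strain_id": [s.strain_id for s in statuses],
                    "virus": [s.virus for s in statuses],
                    "present": [int(s.present) for s in statuses],
                    "pcr_genotype": [s.pcr_genotype for s in statuses],
                    "cdna_signal": [int(s.cdna_signal) for s in statuses],
                }
            ),
        },
        RESULTS,
    )
    print(summary.to_string(index=False))
    print(f"dependency/exclusion violations: {len(violations)}")
    m28 = summary.loc[summary["virus"] == "M28"]
    if int(m28["n_cdna_signal"].item()) > 0:
        print(
            f"note: {int(m28['n_cdna_signal'].item())} strain(s) show a masked "
            "M28 nuclear-cDNA PCR signal without the satellite"
        )
    print(f"tables written to {RESULTS}/virome_summary.tsv and virome_calls.tsv")


if __name__ == "__main__":
    main()
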