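"""Contingency statistics: virus co-occurrence and the genotype-level link.

Screens pairwise virus/satellite co-occurrence in the cohort with Fisher's
exact test (BH-corrected), and tests the published PCR-genotype-by-
abundance-level table with the margin-conditional exact test.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_or_build  # noqa: E402

from killerome import io  # noqa: E402
from killerome.datasets import load_lbc_genotype_table  # noqa: E402
from killerome.stats import cooccurrence_screen, rxc_exact  # noqa: E402
from killerome.types import VirusStatus  # noqa: E402
from killerome.virome import status_from_panel  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort, _ = load_or_build(args.seed)
    statuses = [status_from_panel(p) for p in cohort.panels]
    m_any: dict[str, bool] = {}
    for s in statuses:
        if s.virus in ("M1", "M2", "M28", "Mlus"):
            m_any[s.strain_id] = m_any.get(s.strain_id, False) or s.present
    pooled = [VirusStatus(sid, "M-any", p) for sid, p in sorted(m_any.items())]
    screen = cooccurrence_screen(
        statuses + pooled,
        [("L-A", "L-BC"), ("L-A", "20S"), ("L-A", "23S"), ("20S", "23S"), ("L-A", "M-any")],
    )
    io.write_report({"cooccurrence": screen}, RESULTS)
    print(screen.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    t2 = load_lbc_genotype_table()
    tab = t2[["n_hi", "n_lo"]].to_numpy()
    tab = tab[tab.sum(axis=1) > 0]
    p = rxc_exact(tab, n_mc=9999, seed=args.seed)
    print(
        f"\npublished PCR-genotype x hi/lo table ({tab.shape[0]} observed genotypes, "
        f"n={tab.sum()}): exact-test p = {p:.4g}"
    )
    print(f"screen written to {RESULTS}/cooccurrence.tsv")


if __name__ == "__main__":
    main()
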