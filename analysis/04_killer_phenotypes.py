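"""Call killer phenotypes and satellite dependence; census the published table.

Derives killer status for every assayed strain from the zone bins, decides
M-satellite dependence from the parent/cured comparison in the cohort, and
reproduces the killer and gel-band counts of the packaged 17-strain
M-satellite summary table.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_or_build  # noqa: E402

from killerome import io  # noqa: E402
from killerome.datasets import load_m_satellite_table  # noqa: E402
from killerome.killer import call_killer, call_m_dependence, parse_killer_label  # noqa: E402
from killerome.types import KillerStatus  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort, _ = load_or_build(args.seed)
    by_killer: dict[str, list] = {}
    for a in cohort.assays:
        by_killer.setdefault(a.killer_id, []).append(a)
    calls = {k: call_killer(v) for k, v in by_killer.items()}
    dep = call_m_dependence(calls["S0001"], calls["S0002"]) if {"S0001", "S0002"} <= calls.keys() else None

    io.write_report(
        {
            "killer_calls": pd.DataFrame(
                {
                    "strain_id": [c.strain_id for c in calls.values()],
                    "status": [c.status.value for c in calls.values()],
                    "max_zone_bin": [c.max_zone_bin for c in calls.values()],
                }
            )
        },
        RESULTS,
    )
    for c in calls.values():
        print(f"  {c.strain_id}: {c.status.value} (max zone {c.max_zone_bin})")
    if dep is not None:
        print(
            f"parent S0001 vs cured S0002: M-dependent={dep.m_dependent}, "
            f"residual killing={dep.residual_killing}"
        )

    t3 = load_m_satellite_table()
    status = {r.strain_id: parse_killer_label(r.killer) for r in t3.itertuples(index=False)}
    n_killer = sum(
        s in (KillerStatus.Kplus, KillerStatus.Kpartial) for _, s in status.values()
    )
    print(
        f"published satellite table: {len(t3)} strains, {n_killer} killers "
        f"(full+partial), {int(t3['gel_band_kb'].notna().sum())} with sub-4.6-kb gel bands, "
        f"{int((t3['m_species'] == 'M1').sum())} M1+, {int((t3['m_species'] == 'Mlus').sum())} Mlus+"
    )
    print(f"killer calls written to {RESULTS}/killer_calls.tsv")


if __name__ == "__main__":
    main()
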