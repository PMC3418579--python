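#!/usr/bin/env python
"""QC the simulated panels and estimate pairwise LD.

Markers failing call rate < 95%, exact-test HWE p < 0.01, or MAF < 5% are
removed per population; r2 and signed LD phase are then estimated by EM
for every within-chromosome marker pair up to 6 Mb apart.
"""

from pathlib import Path

from ldphasekit.ld import pairwise_ld
from ldphasekit.panel_io import read_ped_map, write_ped_map, write_table
from ldphasekit.qc import apply_qc

RUN = Path("results/run")


def main() -> None:
    for label in ("breedA", "breedB", "crossbred"):
        panel, mmap = read_ped_map(RUN / f"{label}.ped", RUN / f"{label}.map")
        panel, mmap, report = apply_qc(panel, mmap)
        print(f"{label}: {len(report.survivors)} of {report.n_input} markers pass QC "
              f"(removed: {report.removal_counts})")
        write_ped_map(panel, mmap, RUN / f"{label}.qc.ped", RUN / f"{label}.qc.map")
        write_table(report.to_frame(), RUN / f"{label}.qc_report.tsv", kind="qc_report")
        rec = pairwise_ld(panel, mmap, max_distance_bp=6_000_000, min_pair_n=30)
        write_table(rec, RUN / f"{label}.ld.tsv", kind="ld")
        print(f"{label}: {len(rec)} marker pairs "
              f"({(~rec['converged']).sum()} non-converged)")


if __name__ == "__main__":
    main()
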