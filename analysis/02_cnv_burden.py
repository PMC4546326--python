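#!/usr/bin/env python
"""Length-binned CNV burden with the sample-permutation null.

Reads the simulated cohort from results/cohort/, tabulates deletion and
duplication events per chromosome and length bin for cases and controls,
and attaches per-sample-normalized case/control ratios with 1000-replicate
permutation p-values.  Writes results/burden.tsv and reports the cells with
the strongest case excess.
"""

from pathlib import Path

from cnvdrive.burden_stats import burden_table
from cnvdrive.cnv_events import segments_to_events
from cnvdrive.formats_io import INTERNAL_DIALECT, read_segments

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cases = read_segments(BASE / "cohort" / "cases.seg", INTERNAL_DIALECT, group="case")
    controls = read_segments(
        BASE / "cohort" / "controls.seg", INTERNAL_DIALECT, group="control"
    )
    events = segments_to_events(cases + controls)
    table = burden_table(
        events,
        sorted({s.sample for s in cases}),
        sorted({s.sample for s in controls}),
        n_replicates=1000,
        seed=1,
    )
    table.to_csv(BASE / "burden.tsv", sep="\t", index=False)
    print(f"{len(events)} events over {len(table)} burden cells -> results/burden.tsv")
    top = table.dropna(subset=["ratio"]).sort_values("p_value").head(5)
    print("strongest case/control imbalances:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
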