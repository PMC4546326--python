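#!/usr/bin/env python
"""Generate the default synthetic paired tumor/normal cohort.

Writes case/control segment profiles (20 + 20 samples on a 3 x 10 Mb toy
genome), 200 gene models, a log2 expression matrix with 10 concordant
planted drivers (and 2 discordant decoys) and toy gene sets, plus the
planted ground truth, under results/cohort/.
"""

from pathlib import Path

from cnvdrive.synthetic_data import SimulationConfig, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    config = SimulationConfig(seed=1)
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, OUT)
    print(f"cohort: {config.n_cases} cases / {config.n_controls} controls, "
          f"{len(cohort.genes)} genes")
    print(f"case segments: {len(cohort.case_segments)}, "
          f"control segments: {len(cohort.control_segments)}")
    print(f"planted drivers: {int(cohort.truth.concordant.sum())} concordant, "
          f"{int((~cohort.truth.concordant).sum())} decoys")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
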