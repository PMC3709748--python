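"""Generate the synthetic study that the downstream analysis steps consume.

Emulates the study design end-to-end: 11 normal vs 128 tumor miRNA
profiles and 11 normal vs 110 tumor gene profiles for discovery, three
target-prediction databases with a planted two-source consensus, a PPI
graph with dedicated first neighbors around planted targets, a GO-like
ontology with one planted enriched term, and an independent 15 vs 101
miRNA matrix for marker evaluation. Ground truth goes to truth.json.
"""

from pathlib import Path

from mirpin.simulate import SimulationConfig, simulate_study

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = SimulationConfig()
    _, truth = simulate_study(config, SEED, OUT)
    print(f"wrote synthetic study to {OUT}")
    print(f"planted: {len(truth.planted_down_mirnas)} down + "
          f"{len(truth.planted_up_mirnas)} up miRNAs, "
          f"{len(truth.planted_pairs)} consensus pairs, "
          f"enriched term {truth.planted_term} in the "
          f"{truth.planted_term_mirna} network")


if __name__ == "__main__":
    main()
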