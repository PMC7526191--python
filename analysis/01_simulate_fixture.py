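"""Simulate the study fixtures: one chromosome with a planted hard sweep
(s = 0.1 in the target population) and one fully neutral control, at the
default conditions (15 + 12 diploids, 2 Mb, ~4000 SNPs, 300 generations
of divergence).  Writes VCF + popmap + GFF3 + truth JSON for each under
results/.
"""

import json
import pathlib

from sweepscan.simulate import SimConfig, emit_fixture, simulate_pair

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    for name, s, seed in [("fixture_sweep", 0.1, 1), ("fixture_neutral", 0.0, 2)]:
        cfg = SimConfig(seed=seed, s=s)
        h, pm, truth = simulate_pair(cfg)
        paths, fails = emit_fixture(h, pm, truth, cfg, RESULTS / name)
        print(f"[{name}] wrote {sorted(paths)} -> {RESULTS / name}")
        print(
            f"  sweep allele at {truth.sweep_position:,} bp: "
            f"target sample frequency {truth.freq_target_sample:.2f}, "
            f"reference {truth.freq_ref_sample:.2f} "
            f"({truth.establishment_retries} establishment retries); "
            f"{len(fails)} sites planted to fail QC"
        )
        (RESULTS / name / "config.json").write_text(
            json.dumps(cfg.__dict__, indent=2, sort_keys=True)
        )


if __name__ == "__main__":
    main()
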