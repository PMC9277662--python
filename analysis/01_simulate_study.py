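"""Generate the synthetic 10-horse study and write its raw inputs.

Draws the study plan (30 specimens: dorsal/palmar MCIII and proximal
sesamoid per horse), simulates each load-displacement record, and writes
records, one volume stack per specimen and one specimen's speckle frames
under results/raw_study/, with the study config hash for reproducibility.
"""
import argparse
from pathlib import Path

from sbmech.pipeline import config_hash, make_fixture_study, write_fixture_files


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-horses", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results/raw_study"))
    args = ap.parse_args()

    cfg = make_fixture_study(args.seed, n_horses=args.n_horses)
    write_fixture_files(cfg, args.out)
    print(f"wrote {len(cfg.specimens)} specimens under {args.out}")
    print(f"config hash: {config_hash(cfg)}")


if __name__ == "__main__":
    main()
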