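"""Baseline-correct and integrate every campaign thermogram.

Binding and dilution traces use the piecewise-linear quiet-window baseline;
per-injection heat tables (µcal, kJ/mol of injectant, molar ratio) are
written to results/heats/.
"""

import argparse

import itcfit as m
from _campaign import RESULTS, load_or_simulate, slugify


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    outdir = RESULTS / "heats"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tg in load_or_simulate(args.seed).items():
        heats = m.integrate_peaks(tg)
        path = outdir / f"{slugify(name)}.csv"
        heats.to_frame().to_csv(path, index=False)
        total = heats.q_ucal.sum()
        print(f"{name:32s} total heat {total:9.3f} µcal -> {path.name}")


if __name__ == "__main__":
    main()
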