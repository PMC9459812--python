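"""Simulate the full ITC campaign with known ground truth.

Generates, per inhibitor, a binding titration at its published K_D/ΔH; a
titrant dilution control; an uninhibited acetylcholine-hydrolysis run at
Km = 48.50 µmol/L; and inhibited hydrolysis runs over a concentration grid
at Ki = 1.12 µmol/L.  Traces (CSV + setup sidecar) go to scratch/ — they
are bulky, regenerable raw data.
"""

import argparse

from _campaign import SCRATCH, simulate_campaign


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    paths = simulate_campaign(args.seed)
    print(f"simulated {len(paths)} thermograms -> {SCRATCH}")
    for name, path in paths.items():
        print(f"  {name:28s} {path.name}")


if __name__ == "__main__":
    main()
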