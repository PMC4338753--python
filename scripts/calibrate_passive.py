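#!/usr/bin/env python
"""Regenerate the passive calibration of the surrogate cell.

Finds the dendritic leak density giving a somatic input resistance of
14 MOhm on the desk-scale surrogate tree (seed 1), then the dendritic
specific capacitance giving a somatic input capacitance of 1090 pF, and
prints the values that are pinned as PassiveParams defaults.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from purkinje.morphology import DENDRITE_TAGS, PassiveParams  # noqa: E402
from purkinje.solver import Model, impedance_from_soma        # noqa: E402
from purkinje.morphology import build_cell                    # noqa: E402
from purkinje.channels import build_default_channelome        # noqa: E402


def measure(g_dend, cm_dend, n_dend, seed):
    p = PassiveParams()
    for t in DENDRITE_TAGS:
        p.g_leak[t] = g_dend
        p.cm_specific[t] = cm_dend
    m = Model(build_cell(n_dend=n_dend, seed=seed, passive=p), p,
              build_default_channelome())
    return impedance_from_soma(m)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-dend", type=int, default=48)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--rin", type=float, default=14.0, help="target MOhm")
    ap.add_argument("--cin", type=float, default=1090.0, help="target pF")
    args = ap.parse_args()

    lo, hi = 2e-5, 4e-4
    cm = 1.62
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        rin, cin = measure(mid, cm, args.n_dend, args.seed)
        if rin > args.rin:
            lo = mid
        else:
            hi = mid
    g_dend = mid
    cm = cm * args.cin / cin
    rin, cin = measure(g_dend, cm, args.n_dend, args.seed)
    print(f"dendritic g_leak = {g_dend:.4e} S/cm^2")
    print(f"dendritic Cm     = {cm:.4f} uF/cm^2")
    print(f"-> Rin = {rin:.2f} MOhm, Cin = {cin:.1f} pF")


if __name__ == "__main__":
    main()
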