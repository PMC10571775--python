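"""Derive and verify the shipped Bell-rate calibration of the catenin gate.

The three-state chain has closed-form equilibrium crossovers: with both
transition distances of step i equal to x_i, the force at which the two
states flanking step i are equally occupied is

    f*_i = kBT * ln(kf_i0 / ku_i0) / (2 * x_i).

The calibration pins f*_1 = 4.5 pN (M1 exposure) and f*_2 = 10 pN (full
unfolding) by fixing the zero-force rate ratios; the absolute rate scale
of step 1 is then chosen so that relaxation from the fully folded state at
the first crossover settles (to within 0.01 occupancy) in a few seconds.
Run this script to regenerate the numbers and confirm they match the
package defaults.
"""

import numpy as np

from hippomech.catenin_gate import (BellParams, crossover_force, relax)

KBT = 4.1     # pN*nm
X1 = 1.0      # nm, M1 exposure transition distance (each direction)
X2 = 2.0      # nm, M2/M3 unfolding transition distance
F1_TARGET = 4.5   # pN
F2_TARGET = 10.0  # pN
KU10 = 0.3    # 1/s, sets the absolute timescale of step 1
KU20 = 0.03   # 1/s


def derive() -> BellParams:
    ratio1 = np.exp(F1_TARGET * 2 * X1 / KBT)
    ratio2 = np.exp(F2_TARGET * 2 * X2 / KBT)
    return BellParams(kf10=KU10 * ratio1, ku10=KU10, xf1=X1, xu1=X1,
                      kf20=KU20 * ratio2, ku20=KU20, xf2=X2, xu2=X2,
                      kBT=KBT)


def main() -> None:
    derived = derive()
    shipped = BellParams()
    for name in ("kf10", "ku10", "xf1", "xu1", "kf20", "ku20", "xf2", "xu2"):
        d, s = getattr(derived, name), getattr(shipped, name)
        flag = "OK" if np.isclose(d, s, rtol=1e-12) else "MISMATCH"
        print(f"{name:6s} derived={d:12.6g} shipped={s:12.6g}  {flag}")
    c12 = crossover_force("C1C2", shipped)
    c23 = crossover_force("C2C3", shipped)
    _, _, settle, ok = relax(c12, shipped)
    print(f"\nC1-C2 crossover: {c12:.3f} pN (target {F1_TARGET})")
    print(f"C2-C3 crossover: {c23:.3f} pN (target {F2_TARGET})")
    print(f"settling at first crossover: {settle:.2f} s (settled={ok})")


if __name__ == "__main__":
    main()
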