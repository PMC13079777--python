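"""Reference transcription of the UTCI offset polynomial, written out
term by term as one literal expression (the operational Fortran layout),
used as the oracle for the packaged exponent-table evaluator.

Variables: ta = air temperature [degC], d = Tmrt - ta [K], va = wind speed
[m/s], pa = water vapour pressure [kPa].
"""


def utci_offset_reference(ta: float, d: float, va: float, pa: float) -> float:
    """UTCI minus Ta for in-envelope scalar inputs."""
    return (
        0.0
        + (6.07562052e-01)
        + (-2.27712343e-02) * ta
        + (8.06470249e-04) * ta**2
        + (-1.54271372e-04) * ta**3
        + (-3.24651735e-06) * ta**4
        + (7.32602852e-08) * ta**5
        + (1.35959073e-09) * ta**6
        + (-2.25836520e+00) * va
        + (8.80326035e-02) * ta * va
        + (2.16844454e-03) * ta**2 * va
        + (-1.53347087e-05) * ta**3 * va
        + (-5.72983704e-07) * ta**4 * va
        + (-2.55090145e-09) * ta**5 * va
        + (-7.51269505e-01) * va**2
        + (-4.08350271e-03) * ta * va**2
        + (-5.21670675e-05) * ta**2 * va**2
        + (1.94544667e-06) * ta**3 * va**2
        + (1.14099531e-08) * ta**4 * va**2
        + (1.58137256e-01) * va**3
        + (-6.57263143e-05) * ta * va**3
        + (2.22697524e-07) * ta**2 * va**3
        + (-4.16117031e-08) * ta**3 * va**3
        + (-1.27762753e-02) * va**4
        + (9.66891875e-06) * ta * va**4
        + (2.52785852e-09) * ta**2 * va**4
        + (4.56306672e-04) * va**5
        + (-1.74202546e-07) * ta * va**5
        + (-5.91491269e-06) * va**6
        + (3.98374029e-01) * d
        + (1.83945314e-04) * ta * d
        + (-1.73754510e-04) * ta**2 * d
        + (-7.60781159e-07) * ta**3 * d
        + (3.77830287e-08) * ta**4 * d
        + (5.43079673e-10) * ta**5 * d
        + (-2.00518269e-02) * va * d
        + (8.92859837e-04) * ta * va * d
        + (3.45433048e-06) * ta**2 * va * d
        + (-3.77925774e-07) * ta**3 * va * d
        + (-1.69699377e-09) * ta**4 * va * d
        + (1.69992415e-04) * va**2 * d
        + (-4.99204314e-05) * ta * va**2 * d
        + (2.47417178e-07) * ta**2 * va**2 * d
        + (1.07596466e-08) * ta**3 * va**2 * d
        + (8.49242932e-05) * va**3 * d
        + (1.35191328e-06) * ta * va**3 * d
        + (-6.21531254e-09) * ta**2 * va**3 * d
        + (-4.99410301e-06) * va**4 * d
        + (-1.89489258e-08) * ta * va**4 * d
        + (8.15300114e-08) * va**5 * d
        + (7.55043090e-04) * d**2
        + (-5.65095215e-05) * ta * d**2
        + (-4.52166564e-07) * ta**2 * d**2
        + (2.46688878e-08) * ta**3 * d**2
        + (2.42674348e-10) * ta**4 * d**2
        + (1.54547250e-04) * va * d**2
        + (5.24110970e-06) * ta * va * d**2
        + (-8.75874982e-08) * ta**2 * va * d**2
        + (-1.50743064e-09) * ta**3 * va * d**2
        + (-1.56236307e-05) * va**2 * d**2
        + (-1.33895614e-07) * ta * va**2 * d**2
        + (2.49709824e-09) * ta**2 * va**2 * d**2
        + (6.51711721e-07) * va**3 * d**2
        + (1.94960053e-09) * ta * va**3 * d**2
        + (-1.00361113e-08) * va**4 * d**2
        + (-1.21206673e-05) * d**3
        + (-2.18203660e-07) * ta * d**3
        + (7.51269482e-09) * ta**2 * d**3
        + (9.79063848e-11) * ta**3 * d**3
        + (1.25006734e-06) * va * d**3
        + (-1.81584736e-09) * ta * va * d**3
        + (-3.52197671e-10) * ta**2 * va * d**3
        + (-3.36514630e-08) * va**2 * d**3
        + (1.35908359e-10) * ta * va**2 * d**3
        + (4.17032620e-10) * va**3 * d**3
        + (-1.30369025e-09) * d**4
        + (4.13908461e-10) * ta * d**4
        + (9.22652254e-12) * ta**2 * d**4
        + (-5.08220384e-09) * va * d**4
        + (-2.24730961e-11) * ta * va * d**4
        + (1.17139133e-10) * va**2 * d**4
        + (6.62154879e-10) * d**5
        + (4.03863260e-13) * ta * d**5
        + (1.95087203e-12) * va * d**5
        + (-4.73602469e-12) * d**6
        + (5.12733497e+00) * pa
        + (-3.12788561e-01) * ta * pa
        + (-1.96701861e-02) * ta**2 * pa
        + (9.99690870e-04) * ta**3 * pa
        + (9.51738512e-06) * ta**4 * pa
        + (-4.66426341e-07) * ta**5 * pa
        + (5.48050612e-01) * va * pa
        + (-3.30552823e-03) * ta * va * pa
        + (-1.64119440e-03) * ta**2 * va * pa
        + (-5.16670694e-06) * ta**3 * va * pa
        + (9.52692432e-07) * ta**4 * va * pa
        + (-4.29223622e-02) * va**2 * pa
        + (5.00845667e-03) * ta * va**2 * pa
        + (1.00601257e-06) * ta**2 * va**2 * pa
        + (-1.81748644e-06) * ta**3 * va**2 * pa
        + (-1.25813502e-03) * va**3 * pa
        + (-1.79330391e-04) * ta * va**3 * pa
        + (2.34994441e-06) * ta**2 * va**3 * pa
        + (1.29735808e-04) * va**4 * pa
        + (1.29064870e-06) * ta * va**4 * pa
        + (-2.28558686e-06) * va**5 * pa
        + (-3.69476348e-02) * d * pa
        + (1.62325322e-03) * ta * d * pa
        + (-3.14279680e-05) * ta**2 * d * pa
        + (2.59835559e-06) * ta**3 * d * pa
        + (-4.77136523e-08) * ta**4 * d * pa
        + (8.64203390e-03) * va * d * pa
        + (-6.87405181e-04) * ta * va * d * pa
        + (-9.13863872e-06) * ta**2 * va * d * pa
        + (5.15916806e-07) * ta**3 * va * d * pa
        + (-3.59217476e-05) * va**2 * d * pa
        + (3.28696511e-05) * ta * va**2 * d * pa
        + (-7.10542454e-07) * ta**2 * va**2 * d * pa
        + (-1.24382300e-05) * va**3 * d * pa
        + (-7.38584400e-09) * ta * va**3 * d * pa
        + (2.20609296e-07) * va**4 * d * pa
        + (-7.32469180e-04) * d**2 * pa
        + (-1.87381964e-05) * ta * d**2 * pa
        + (4.80925239e-06) * ta**2 * d**2 * pa
        + (-8.75492040e-08) * ta**3 * d**2 * pa
        + (2.77862930e-05) * va * d**2 * pa
        + (-5.06004592e-06) * ta * va * d**2 * pa
        + (1.14325367e-07) * ta**2 * va * d**2 * pa
        + (2.53016723e-06) * va**2 * d**2 * pa
        + (-1.72857035e-08) * ta * va**2 * d**2 * pa
        + (-3.95079398e-08) * va**3 * d**2 * pa
        + (-3.59413173e-07) * d**3 * pa
        + (7.04388046e-07) * ta * d**3 * pa
        + (-1.89309167e-08) * ta**2 * d**3 * pa
        + (-4.79768731e-07) * va * d**3 * pa
        + (7.96079978e-09) * ta * va * d**3 * pa
        + (1.62897058e-09) * va**2 * d**3 * pa
        + (3.94367674e-08) * d**4 * pa
        + (-1.18566247e-09) * ta * d**4 * pa
        + (3.34678041e-10) * va * d**4 * pa
        + (-1.15606447e-10) * d**5 * pa
        + (-2.80626406e+00) * pa**2
        + (5.48712484e-01) * ta * pa**2
        + (-3.99428410e-03) * ta**2 * pa**2
        + (-9.54009191e-04) * ta**3 * pa**2
        + (1.93090978e-05) * ta**4 * pa**2
        + (-3.08806365e-01) * va * pa**2
        + (1.16952364e-02) * ta * va * pa**2
        + (4.95271903e-04) * ta**2 * va * pa**2
        + (-1.90710882e-05) * ta**3 * va * pa**2
        + (2.10787756e-03) * va**2 * pa**2
        + (-6.98445738e-04) * ta * va**2 * pa**2
        + (2.30109073e-05) * ta**2 * va**2 * pa**2
        + (4.17856590e-04) * va**3 * pa**2
        + (-1.27043871e-05) * ta * va**3 * pa**2
        + (-3.04620472e-06) * va**4 * pa**2
        + (5.14507424e-02) * d * pa**2
        + (-4.32510997e-03) * ta * d * pa**2
        + (8.99281156e-05) * ta**2 * d * pa**2
        + (-7.14663943e-07) * ta**3 * d * pa**2
        + (-2.66016305e-04) * va * d * pa**2
        + (2.63789586e-04) * ta * va * d * pa**2
        + (-7.01199003e-06) * ta**2 * va * d * pa**2
        + (-1.06823306e-04) * va**2 * d * pa**2
        + (3.61341136e-06) * ta * va**2 * d * pa**2
        + (2.29748967e-07) * va**3 * d * pa**2
        + (3.04788893e-04) * d**2 * pa**2
        + (-6.42070836e-05) * ta * d**2 * pa**2
        + (1.16257971e-06) * ta**2 * d**2 * pa**2
        + (7.68023384e-06) * va * d**2 * pa**2
        + (-5.47446896e-07) * ta * va * d**2 * pa**2
        + (-3.59937910e-08) * va**2 * d**2 * pa**2
        + (-4.36497725e-06) * d**3 * pa**2
        + (1.68737969e-07) * ta * d**3 * pa**2
        + (2.67489271e-08) * va * d**3 * pa**2
        + (3.23926897e-09) * d**4 * pa**2
        + (-3.53874123e-02) * pa**3
        + (-2.21201190e-01) * ta * pa**3
        + (1.55126038e-02) * ta**2 * pa**3
        + (-2.63917279e-04) * ta**3 * pa**3
        + (4.53433455e-02) * va * pa**3
        + (-4.32943862e-03) * ta * va * pa**3
        + (1.45389826e-04) * ta**2 * va * pa**3
        + (2.17508610e-04) * va**2 * pa**3
        + (-6.66724702e-05) * ta * va**2 * pa**3
        + (3.33217140e-05) * va**3 * pa**3
        + (-2.26921615e-03) * d * pa**3
        + (3.80261982e-04) * ta * d * pa**3
        + (-5.45314314e-09) * ta**2 * d * pa**3
        + (-7.96355448e-04) * va * d * pa**3
        + (2.53458034e-05) * ta * va * d * pa**3
        + (-6.31223658e-06) * va**2 * d * pa**3
        + (3.02122035e-04) * d**2 * pa**3
        + (-4.77403547e-06) * ta * d**2 * pa**3
        + (1.73825715e-06) * va * d**2 * pa**3
        + (-4.09087898e-07) * d**3 * pa**3
        + (6.14155345e-01) * pa**4
        + (-6.16755931e-02) * ta * pa**4
        + (1.33374846e-03) * ta**2 * pa**4
        + (3.55375387e-03) * va * pa**4
        + (-5.13027851e-04) * ta * va * pa**4
        + (1.02449757e-04) * va**2 * pa**4
        + (-1.48526421e-03) * d * pa**4
        + (-4.11469183e-05) * ta * d * pa**4
        + (-6.80434415e-06) * va * d * pa**4
        + (-9.77675906e-06) * d**2 * pa**4
        + (8.82773108e-02) * pa**5
        + (-3.01859306e-03) * ta * pa**5
        + (1.04452989e-03) * va * pa**5
        + (2.47090539e-04) * d * pa**5
        + (1.48348065e-03) * pa**6
    )
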