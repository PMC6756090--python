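"""Independent extended-precision re-implementation of the belief updates.

A deliberately naive, trial-at-a-time transliteration of the update
equations using 50-digit mpmath arithmetic. It shares no code with the
package implementation and serves as the numerical oracle in tests.
"""

import mpmath as mp

mp.mp.dps = 50

EPS = mp.mpf("1e-8")


def oracle_filter(inputs, kappa, omega, theta, mu2_0, sigma2_0, mu3_0, sigma3_0):
    """Return per-trial dicts of all filter quantities at high precision."""
    kappa, omega, theta = mp.mpf(kappa), mp.mpf(omega), mp.mpf(theta)
    mu2, sigma2 = mp.mpf(mu2_0), mp.mpf(sigma2_0)
    mu3, sigma3 = mp.mpf(mu3_0), mp.mpf(sigma3_0)
    rows = []
    for u in inputs:
        u = mp.mpf(int(u))
        muhat1 = 1 / (1 + mp.e**(-mu2))
        muhat1 = min(max(muhat1, EPS), 1 - EPS)
        pihat1 = 1 / (muhat1 * (1 - muhat1))
        delta1 = u - muhat1

        vol = mp.e**(kappa * mu3 + omega)
        sigmahat2 = sigma2 + vol
        pihat2 = 1 / sigmahat2
        pi2 = pihat2 + muhat1 * (1 - muhat1)
        sigma2_new = 1 / pi2
        mu2_new = mu2 + sigma2_new * delta1

        delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / sigmahat2 - 1
        w2 = vol / sigmahat2
        pihat3 = 1 / (sigma3 + theta)
        pi3 = pihat3 + (kappa**2 / 2) * w2 * (w2 + (2 * w2 - 1) * delta2)
        if pi3 <= 0:
            raise ValueError("non-positive level-3 precision")
        sigma3_new = 1 / pi3
        mu3_new = mu3 + sigma3_new * (kappa / 2) * w2 * delta2

        rows.append(
            {
                "muhat1": muhat1, "pihat1": pihat1, "delta1": delta1,
                "sigmahat2": sigmahat2, "pihat2": pihat2, "pi2": pi2,
                "sigma2": sigma2_new, "mu2": mu2_new, "delta2": delta2,
                "pihat3": pihat3, "pi3": pi3, "sigma3": sigma3_new,
                "mu3": mu3_new,
            }
        )
        mu2, sigma2 = mu2_new, sigma2_new
        mu3, sigma3 = mu3_new, sigma3_new
    return rows
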