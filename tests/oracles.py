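"""Independent brute-force scalar evaluators used as oracles.

These are deliberately naive, pure-Python transcriptions of the published
formulas, written and maintained separately from the package so the tests
check the implementation against an independent path.
"""

import math


def dr_oracle(doy):
    return 1 + 0.033 * math.cos(doy * 2 * math.pi / 365)


def cos_theta_oracle(elev_deg):
    phi = elev_deg * math.pi / 180
    return math.cos(math.pi / 2 - phi)


def tetens_oracle(t_C):
    return 0.6108 * math.exp(17.27 * t_C / (t_C + 237.3))


def w_oracle(ea, pair):
    return 0.14 * ea * pair + 2.1


def tau_b_oracle(pair, kt, cos_theta, w):
    return 0.98 * math.exp(
        -0.00146 * pair / (kt * cos_theta) - 0.075 * (w / cos_theta) ** 0.4
    )


def tau_d_oracle(tau_b):
    if tau_b >= 0.15:
        return 0.35 - 0.36 * tau_b
    return 0.18 + 0.82 * tau_b


def eps_a_oracle(tau_sw):
    return 0.85 * (-math.log(tau_sw)) ** 0.09


def gamma_oracle(pair):
    return 1.013e-3 * pair / (0.622 * 2.45)


def delta_oracle(t_C):
    return 4098 * (0.6108 * math.exp(17.27 * t_C / (t_C + 237.3))) / (t_C + 237.3) ** 2


def albedo_oracle(r2, r3, r4, r5, r6, r7):
    return (
        0.254 * r2 + 0.149 * r3 + 0.147 * r4 + 0.311 * r5 + 0.103 * r6 + 0.036 * r7
    )


def rs_down_oracle(cos_theta, dr, tau_sw):
    return 1367 * cos_theta * dr * tau_sw


def stefan_oracle(eps, t_K):
    return eps * 5.67e-8 * t_K**4


def eps0_oracle(ndvi):
    # log law for vegetated/soil pixels only (ndvi > 0), no clipping
    return 1.009 + 0.047 * math.log(ndvi)


def rn_oracle(albedo, rs, rld, rlu, eps0):
    return (1 - albedo) * rs + rld - rlu - (1 - eps0) * rld


def g_ratio_oracle(ts_C, albedo, ndvi):
    return (ts_C / albedo) * (0.0038 * albedo + 0.0074 * albedo**2) * (
        1 - 0.98 * ndvi**4
    )


def fr_oracle(ndvi, ndvi_min, ndvi_max):
    return ((ndvi - ndvi_min) / (ndvi_max - ndvi_min)) ** 2


def phi_oracle(ts, fr, t_max, t_min):
    phi_min = 1.26 * fr
    return (t_max - ts) / (t_max - t_min) * (1.26 - phi_min) + phi_min


def le_oracle(phi, rn, g, delta, gamma):
    return phi * (rn - g) * delta / (delta + gamma)


def et_i_oracle(le):
    return 3600 * le / 2.45e6


def et_d_oracle(alpha, ef, energy_d):
    return alpha * ef * energy_d / 2.45


# --- validation statistics, brute-force loops ------------------------------

def _mean(xs):
    return sum(xs) / len(xs)


def r2_oracle(y, yhat):
    yb, yhb = _mean(y), _mean(yhat)
    cov = _mean([(a - yb) * (b - yhb) for a, b in zip(y, yhat)])
    sy = math.sqrt(_mean([(a - yb) ** 2 for a in y]))
    syh = math.sqrt(_mean([(b - yhb) ** 2 for b in yhat]))
    return (cov / (sy * syh)) ** 2


def rmse_oracle(y, yhat):
    return math.sqrt(_mean([(a - b) ** 2 for a, b in zip(y, yhat)]))


def d_oracle(y, yhat):
    yb = _mean(y)
    num = sum((a - b) ** 2 for a, b in zip(y, yhat))
    den = sum((abs(b - yb) + abs(a - yb)) ** 2 for a, b in zip(y, yhat))
    return 1 - num / den


def nsme_oracle(y, yhat):
    yb = _mean(y)
    return 1 - sum((a - b) ** 2 for a, b in zip(y, yhat)) / sum(
        (a - yb) ** 2 for a in y
    )


def mbe_oracle(y, yhat):
    return _mean([a - b for a, b in zip(y, yhat)])
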