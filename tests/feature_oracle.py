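"""Independent, loop-based reference implementations of the 22 features.

Written deliberately without numpy vectorization (plain Python loops and the
math/cmath modules) so the package's vectorized implementations are checked
against a genuinely separate code path.
"""

from __future__ import annotations

import cmath
import math


def _enh_p(i: int, n: int) -> float:
    return 0.75 if 0.2 * n <= i <= 0.8 * n else 0.5


def oracle_features(x, fzc_t=0.01, wa_t=0.01, myop_t=0.016, card_t=0.01,
                    v=2.0, eps=1e-10) -> dict:
    x = [float(v_) for v_ in x]
    n = len(x)
    assert n >= 2

    iemg = sum(abs(v_) for v_ in x)
    mav = iemg / n
    rms = math.sqrt(sum(v_ * v_ for v_ in x) / n)

    mmav = 0.0
    mmav2 = 0.0
    emav = 0.0
    asm_c = 0 + 0j
    ass_c = 0 + 0j
    ld_acc = 0.0
    vo_acc = 0.0
    for i in range(1, n + 1):
        xi = x[i - 1]
        if 0.25 * n <= i <= 0.75 * n:
            w1, w2 = 1.0, 1.0
        elif i < 0.25 * n:
            w1, w2 = 0.5, 4.0 * i / n
        else:
            w1, w2 = 0.5, 4.0 * (n - i) / n
        mmav += w1 * abs(xi)
        mmav2 += w2 * abs(xi)
        p = _enh_p(i, n)
        emav += abs(xi) ** p
        asm_c += complex(xi) ** p
        ass_c += complex(xi) ** 0.5
        ld_acc += math.log(abs(xi) + eps)
        vo_acc += abs(xi) ** v
    mmav /= n
    mmav2 /= n
    emav /= n
    vo = (vo_acc / n) ** (1.0 / v)
    ld = math.exp(ld_acc / n)
    asm = abs(asm_c)
    ass = abs(ass_c)

    ewl = 0.0
    damv = 0.0
    dasdv = 0.0
    for i in range(2, n + 1):
        d = x[i - 1] - x[i - 2]
        ewl += abs(d) ** _enh_p(i, n)
        damv += abs(d)
        dasdv += d * d
    damv /= n - 1
    dasdv = math.sqrt(dasdv / (n - 1))
    ldamv = math.log(damv + eps)
    ldasdv = math.log(dasdv + eps)

    fzc = 0
    wa = 0
    for i in range(n - 1):
        d = x[i + 1] - x[i]
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= fzc_t:
            fzc += 1
        if abs(d) >= wa_t:
            wa += 1
    myop = sum(1 for v_ in x if abs(v_) >= myop_t) / n
    s = sorted(x)
    card = sum(1 for i in range(n - 1) if abs(s[i] - s[i + 1]) > card_t)

    mean = sum(x) / n
    sd = math.sqrt(sum((v_ - mean) ** 2 for v_ in x) / (n - 1))
    mad = sum(abs(v_ - mean) for v_ in x) / n
    iqr = _quantile(s, 0.75) - _quantile(s, 0.25)
    m2 = sum((v_ - mean) ** 2 for v_ in x) / n
    m4 = sum((v_ - mean) ** 4 for v_ in x) / n
    kurt = m4 / (m2 * m2) if m2 > 0 else float("nan")
    denom = mean if mean != 0.0 else eps
    cov = sd / denom

    return {
        "FZC": float(fzc), "EWL": ewl, "EMAV": emav, "ASM": asm, "ASS": ass,
        "CARD": float(card), "LDASDV": ldasdv, "LDAMV": ldamv, "MYOP": myop,
        "VO": vo, "MMAV": mmav, "MMAV2": mmav2, "IEMG": iemg, "RMS": rms,
        "WA": float(wa), "LD": ld, "MAV": mav, "MAD": mad, "IQR": iqr,
        "KURT": kurt, "COV": cov, "SD": sd,
    }


def _quantile(sorted_x, q: float) -> float:
    """Linear-interpolation quantile on a pre-sorted list."""
    n = len(sorted_x)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])
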