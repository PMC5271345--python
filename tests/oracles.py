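"""Independent oracles for the test suite.

Literal transcriptions of the published score formulas operating on plain
floats, plus a brute-force pairwise AUROC. Deliberately share no code with
the package: every clamp and substitution is written out inline so these can
catch transcription errors in the implementation.
"""

import math


def meld_oracle(cr_mgdl, bili_mgdl, inr, dialysis=False):
    if dialysis:
        cr_mgdl = 4.0
    cr = min(max(cr_mgdl, 1.0), 4.0)
    bili = max(bili_mgdl, 1.0)
    i = max(inr, 1.0)
    raw = 10 * (0.957 * math.log(cr) + 0.378 * math.log(bili) + 1.120 * math.log(i) + 0.643)
    return min(int(math.floor(raw + 0.5)), 40)


def meso_oracle(cr_mgdl, bili_mgdl, inr, na, dialysis=False):
    return meld_oracle(cr_mgdl, bili_mgdl, inr, dialysis) / na * 10


def meld_na_oracle(cr_mgdl, bili_mgdl, inr, na, dialysis=False):
    na = min(max(na, 125.0), 140.0)
    m = meld_oracle(cr_mgdl, bili_mgdl, inr, dialysis)
    return int(math.floor(m - na - 0.025 * m * (140 - na) + 140 + 0.5))


def ukeld_oracle(cr_umoll, bili_umoll, inr, na):
    cr = min(max(cr_umoll, 1.0), 400.0)
    na = min(max(na, 112.0), 150.0)
    bili = max(bili_umoll, 1.0)
    i = max(inr, 1.0)
    return (
        1.485 * math.log(cr)
        + 3.13 * math.log(bili)
        + 5.395 * math.log(i)
        - 81.565 * math.log(na)
        + 435
    )


def imeld_oracle(cr_mgdl, bili_mgdl, inr, na, age, dialysis=False):
    return meld_oracle(cr_mgdl, bili_mgdl, inr, dialysis) + age * 0.3 - 0.7 * na + 100


def refit_meld_oracle(cr_mgdl, bili_mgdl, inr, dialysis=False):
    if dialysis:
        cr_mgdl = 3.0
    cr = min(max(cr_mgdl, 0.8), 3.0)
    bili = max(bili_mgdl, 1.0)
    i = min(max(inr, 1.0), 3.0)
    return 8.485 * math.log(cr) + 4.082 * math.log(bili) + 10.671 * math.log(i) + 7.432


def refit_meld_na_oracle(cr_mgdl, bili_mgdl, inr, na, dialysis=False):
    if dialysis:
        cr_mgdl = 3.0
    cr = min(max(cr_mgdl, 0.8), 3.0)
    bili = max(bili_mgdl, 1.0)
    i = min(max(inr, 1.0), 3.0)
    na = min(max(na, 125.0), 140.0)
    bili_cc = min(bili, 20.0)
    return (
        6.792 * math.log(cr)
        + 4.258 * math.log(bili)
        + 8.29 * math.log(i)
        + 0.652 * (140 - na)
        - 0.194 * (140 - na) * bili_cc
        + 6.327
    )


def up_meld_oracle(cr_mgdl, bili_mgdl, inr, dialysis=False):
    # dialysis never substitutes creatinine for this score
    cr = min(max(cr_mgdl, 1.0), 4.0)
    bili = max(bili_mgdl, 1.0)
    i = max(inr, 1.0)
    return 1.266 * math.log(1 + cr) + 0.939 * math.log(1 + bili) + 1.658 * math.log(1 + i)


def peld_oracle(alb_gdl, bili_mgdl, inr, age_years, growth_failure):
    age_ind = 1 if age_years < 1 else 0
    gf = 1 if (growth_failure and age_years * 12 <= 219) else 0
    return (
        0.436 * age_ind
        - 0.687 * math.log(alb_gdl)
        + 0.480 * math.log(bili_mgdl)
        + 1.857 * math.log(inr)
        + 0.667 * gf
    ) * 10


def auroc_bruteforce(scores, events):
    """Mean over all event/non-event pairs of 1/0.5/0 (win/tie/loss)."""
    pos = [s for s, e in zip(scores, events) if e]
    neg = [s for s, e in zip(scores, events) if not e]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))
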