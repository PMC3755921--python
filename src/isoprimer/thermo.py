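"""Nearest-neighbor oligo thermodynamics and primer hygiene filters.

Melting temperatures use the unified nearest-neighbor DNA/DNA parameter set
(SantaLucia 1998) with duplex-initiation and terminal-A/T corrections:

    Tm = 1000 * dH / (dS_salt + R * ln(CT / 4)) - 273.15        [K -> degC]
    dS_salt = dS + 0.368 * (N - 1) * ln[Na+]

with dH in kcal/mol, dS in cal/(mol K), R = 1.9872 cal/(mol K), CT the total
oligo concentration (non-self-complementary duplex, primer in excess over
template, hence CT/4), [Na+] the monovalent cation molarity and N the oligo
length.  ``tm_windows`` evaluates the same model for every fixed-length
window of a template in O(n) via prefix sums, which is what the design
enumerator uses.

Structural filters implement standard primer hygiene: mononucleotide runs,
self-dimers (antiparallel complementary runs, including 3'-anchored ones),
hairpins (stem + loop >= 3), GC content, and ambiguity codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

R_GAS = 1.9872  # cal / (mol K)

# Unified NN set: dinucleotide (5'->3', top strand) -> (dH kcal/mol, dS cal/mol/K)
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# terminal (initiation) corrections per duplex end
_END_AT = (2.3, 4.1)
_END_GC = (0.1, -2.8)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside A/C/G/T or has invalid length."""


def _validate(seq: str, min_len: int = 8, max_len: int = 36) -> str:
    seq = seq.upper()
    if not min_len <= len(seq) <= max_len:
        raise InvalidSequenceError(
            f"length {len(seq)} outside [{min_len}, {max_len}]: {seq!r}"
        )
    if set(seq) - set(_BASES):
        raise InvalidSequenceError(f"invalid alphabet in {seq!r}")
    return seq


def melting_temperature(
    seq: str, monovalent_salt: float = 0.05, oligo_conc: float = 250e-9
) -> float:
    """Nearest-neighbor Tm (degC) of ``seq`` against its perfect complement.

    ``monovalent_salt`` is the Na+ molarity (default 50 mM) and ``oligo_conc``
    the total primer concentration in M (default 250 nM).
    """
    seq = _validate(seq)
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inc = _END_AT if end in "AT" else _END_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(monovalent_salt)
    return 1000.0 * dh / (ds_salt + R_GAS * math.log(oligo_conc / 4.0)) - 273.15


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as uint8 0..3 (N and other codes become 255)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


_NN_DH = np.zeros(16)
_NN_DS = np.zeros(16)
for _din, (_h, _s) in NN_PARAMS.items():
    _idx = 4 * _BASE_INDEX[_din[0]] + _BASE_INDEX[_din[1]]
    _NN_DH[_idx] = _h
    _NN_DS[_idx] = _s


def tm_windows(
    template: str,
    length: int,
    monovalent_salt: float = 0.05,
    oligo_conc: float = 250e-9,
) -> np.ndarray:
    """Tm of every ``length``-window of ``template`` (NaN where a window has N).

    Identical model to :func:`melting_temperature`, vectorized via prefix sums
    over dinucleotide stacks.
    """
    b = encode(template)
    n = len(b)
    if n < length:
        return np.empty(0)
    valid = b != 255
    b_safe = np.where(valid, b, 0).astype(np.int64)
    stacks = 4 * b_safe[:-1] + b_safe[1:]
    dh_pref = np.concatenate([[0.0], np.cumsum(_NN_DH[stacks])])
    ds_pref = np.concatenate([[0.0], np.cumsum(_NN_DS[stacks])])
    ok_pref = np.concatenate([[0], np.cumsum(~valid)])

    starts = np.arange(n - length + 1)
    ends = starts + length
    dh = dh_pref[ends - 1] - dh_pref[starts]
    ds = ds_pref[ends - 1] - ds_pref[starts]
    at_left = (b_safe[starts] == 0) | (b_safe[starts] == 3)
    at_right = (b_safe[ends - 1] == 0) | (b_safe[ends - 1] == 3)
    dh = dh + np.where(at_left, _END_AT[0], _END_GC[0]) + np.where(
        at_right, _END_AT[0], _END_GC[0]
    )
    ds = ds + np.where(at_left, _END_AT[1], _END_GC[1]) + np.where(
        at_right, _END_AT[1], _END_GC[1]
    )
    ds_salt = ds + 0.368 * (length - 1) * math.log(monovalent_salt)
    tm = 1000.0 * dh / (ds_salt + R_GAS * math.log(oligo_conc / 4.0)) - 273.15
    has_n = (ok_pref[ends] - ok_pref[starts]) > 0
    return np.where(has_n, np.nan, tm)


def gc_windows(template: str, length: int) -> np.ndarray:
    b = encode(template)
    gc = np.concatenate([[0], np.cumsum((b == 1) | (b == 2))])
    starts = np.arange(len(b) - length + 1)
    return (gc[starts + length] - gc[starts]) / length


# ---------------------------------------------------------------------------
# structural filters


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.passed


def max_polyrun(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def has_self_dimer(seq: str, max_run: int = 8) -> bool:
    """True if ``seq`` can pair with a second copy of itself (antiparallel)
    over >= ``max_run`` contiguous complementary bases."""
    k = max_run
    if len(seq) < k:
        return False
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    for mer in kmers:
        rc = "".join(_COMP[c] for c in reversed(mer))
        if rc in kmers:
            return True
    return False


def has_hairpin(seq: str, min_stem: int = 6, min_loop: int = 3) -> bool:
    """True if ``seq`` folds on itself with a stem >= ``min_stem`` separated
    by a loop of >= ``min_loop`` unpaired bases."""
    k = min_stem
    if len(seq) < 2 * k + min_loop:
        return False
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)
    for i in range(len(seq) - k + 1):
        rc = "".join(_COMP[c] for c in reversed(seq[i : i + k]))
        for j in positions.get(rc, ()):
            if j - (i + k) >= min_loop:
                return True
    return False


def structural_filters(seq: str, params) -> FilterResult:
    """Apply primer hygiene filters; ``params`` is a DesignParams-like object.

    Reason codes: ambiguous, polyrun, gc_range, self_dimer, hairpin.
    """
    seq = seq.upper()
    reasons: list[str] = []
    if set(seq) - set(_BASES):
        reasons.append("ambiguous")
    else:
        if max_polyrun(seq) > params.max_polyrun:
            reasons.append("polyrun")
        gc = gc_fraction(seq)
        if not params.gc_min <= gc <= params.gc_max:
            reasons.append("gc_range")
        if has_self_dimer(seq, params.dimer_max_run):
            reasons.append("self_dimer")
        if has_hairpin(seq, params.hairpin_max_stem, params.hairpin_min_loop):
            reasons.append("hairpin")
    return FilterResult(passed=not reasons, reasons=tuple(reasons))
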