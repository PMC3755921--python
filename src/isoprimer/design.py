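"""Primer pair enumeration, scoring and selection within common CDS regions.

Candidate primers are all template windows of 18-25 nt that pass Tm
(57-63 degC), GC (0.35-0.65) and structural filters; candidate pairs are all
(forward, reverse) window combinations whose predicted product falls in
50-250 bp.  Each pair gets a deterministic penalty

    sum over both primers of |Tm - Tm_opt| + 0.5 * |len - len_opt|
                             + 10 * [GC outside range]
    + |Tm_fwd - Tm_rev| + 0.01 * |product - product_opt|

and selection keeps up to ``k`` gene-specific pairs with a greedy amplicon
diversity rule (each new amplicon must overlap every accepted one by < 50%
of the shorter amplicon), falling back to the best remaining specific pairs
when diversity cannot be satisfied.

``enumerate_pairs`` materializes the full candidate list (used on short
segments and for oracle comparison); ``iter_ranked_pairs`` yields the same
candidates lazily in exact penalty order so the pipeline can classify
specificity only for the candidates it actually inspects.
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass, fields, replace
from typing import Callable, Iterable, Iterator

import numpy as np

from . import thermo


@dataclass(frozen=True)
class DesignParams:
    """All tunable design knobs with their defaults.

    Lengths in nt, temperatures in degC, concentrations in M, GC as fraction.
    """

    primer_len_min: int = 18
    primer_len_max: int = 25
    primer_len_opt: int = 20
    tm_min: float = 57.0
    tm_max: float = 63.0
    tm_opt: float = 60.0
    gc_min: float = 0.35
    gc_max: float = 0.65
    product_min: int = 50
    product_max: int = 250
    product_opt: int = 110
    k: int = 3
    max_polyrun: int = 4
    monovalent_salt: float = 0.05
    oligo_conc: float = 250e-9
    dimer_max_run: int = 8
    hairpin_max_stem: int = 6
    hairpin_min_loop: int = 3
    min_template: int = 60
    max_product_scan: int = 1000
    max_classified: int = 200
    # binding-site rules (see specificity module)
    identity_min: float = 0.8
    max_mm_3p12: int = 1
    max_mm_3p3: int = 0

    @classmethod
    def from_file(cls, path) -> "DesignParams":
        """Read flat ``key = value`` lines (# comments allowed)."""
        types = {f.name: f.type for f in fields(cls)}
        overrides = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"unknown design parameter {key!r}")
                caster = int if types[key] == "int" else float
                overrides[key] = caster(value.strip())
        return cls(**overrides)

    def with_overrides(self, **kwargs) -> "DesignParams":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class Primer:
    seq: str  # 5'->3'
    orientation: str  # forward | reverse
    start: int  # transcript coord of the binding site's leftmost base
    length: int
    tm: float
    gc: float


@dataclass
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_length: int
    penalty: float
    design_source: str = "common_exon"  # common_exon | junction_span
    pair_id: str = ""

    @property
    def amplicon_start(self) -> int:
        return self.forward.start

    @property
    def amplicon_end(self) -> int:
        return self.forward.start + self.product_length

    @property
    def key(self) -> tuple:
        return (self.penalty, self.amplicon_start, self.forward.seq, self.reverse.seq)


def stable_pair_id(gene_id: str, pair: PrimerPair) -> str:
    """Deterministic, input-order-independent pair id ('PP' + integer)."""
    digest = zlib.crc32(f"{gene_id}:{pair.forward.seq}:{pair.reverse.seq}".encode())
    return f"PP{digest}"


# ---------------------------------------------------------------------------
# window table


def _window_table(segment_seq: str, params: DesignParams):
    """All primer windows of the segment passing per-primer filters.

    Returns parallel numpy arrays (start, end, length, tm, gc, base penalty)
    sorted by (start, length).  Tm of a window equals the Tm of its reverse
    complement (duplex symmetry), so the same table serves both orientations.
    """
    starts, lens, tms, gcs = [], [], [], []
    n = len(segment_seq)
    for L in range(params.primer_len_min, params.primer_len_max + 1):
        if n < L:
            continue
        tm = thermo.tm_windows(segment_seq, L, params.monovalent_salt, params.oligo_conc)
        gc = thermo.gc_windows(segment_seq, L)
        ok = (
            ~np.isnan(tm)
            & (tm >= params.tm_min)
            & (tm <= params.tm_max)
            & (gc >= params.gc_min)
            & (gc <= params.gc_max)
        )
        for i in np.nonzero(ok)[0]:
            window = segment_seq[i : i + L]
            if not thermo.structural_filters(window, params):
                continue
            starts.append(int(i))
            lens.append(L)
            tms.append(float(tm[i]))
            gcs.append(float(gc[i]))
    if not starts:
        empty = np.empty(0)
        return (np.empty(0, int),) * 3 + (empty, empty, empty)
    order = np.lexsort((np.array(lens), np.array(starts)))
    s = np.array(starts)[order]
    l = np.array(lens)[order]
    tm_a = np.array(tms)[order]
    gc_a = np.array(gcs)[order]
    base_pen = np.abs(tm_a - params.tm_opt) + 0.5 * np.abs(l - params.primer_len_opt)
    # GC outside range never survives the filter, but keep the scoring term
    # so the penalty formula is complete if filters are relaxed by a caller.
    base_pen = base_pen + 10.0 * ((gc_a < params.gc_min) | (gc_a > params.gc_max))
    return s, s + l, l, tm_a, gc_a, base_pen


def _pair_arrays(segment_seq: str, params: DesignParams):
    s, e, l, tm, gc, pen1 = _window_table(segment_seq, params)
    m = len(s)
    if m == 0:
        return None
    # pair forward a with reverse b iff e[b] - s[a] is in the product range;
    # resolved per-forward over end-sorted windows to stay O(pairs), not O(m^2)
    e_order = np.argsort(e, kind="stable")
    e_sorted = e[e_order]
    lo = np.searchsorted(e_sorted, s + params.product_min, side="left")
    hi = np.searchsorted(e_sorted, s + params.product_max, side="right")
    counts = hi - lo
    a_idx = np.repeat(np.arange(m), counts)
    if len(a_idx) == 0:
        return None
    b_idx = np.concatenate([e_order[l_:h_] for l_, h_ in zip(lo, hi) if h_ > l_])
    products = e[b_idx] - s[a_idx]
    penalty = (
        pen1[a_idx]
        + pen1[b_idx]
        + np.abs(tm[a_idx] - tm[b_idx])
        + 0.01 * np.abs(products - params.product_opt)
    )
    return {
        "windows": (s, e, l, tm, gc),
        "a": a_idx,
        "b": b_idx,
        "product": products,
        "penalty": penalty,
    }


def _materialize(segment_seq: str, offset: int, arrays, i: int,
                 params: DesignParams) -> PrimerPair:
    s, e, l, tm, gc = arrays["windows"]
    a = int(arrays["a"][i])
    b = int(arrays["b"][i])
    fwd_window = segment_seq[s[a] : e[a]]
    rev_window = segment_seq[s[b] : e[b]]
    forward = Primer(
        seq=fwd_window,
        orientation="forward",
        start=offset + int(s[a]),
        length=int(l[a]),
        tm=float(tm[a]),
        gc=float(gc[a]),
    )
    reverse = Primer(
        seq=_revcomp(rev_window),
        orientation="reverse",
        start=offset + int(s[b]),
        length=int(l[b]),
        tm=float(tm[b]),
        gc=float(gc[b]),
    )
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        product_length=int(arrays["product"][i]),
        penalty=float(arrays["penalty"][i]),
    )


def enumerate_pairs(segment_seq: str, params: DesignParams | None = None,
                    offset: int = 0) -> list[PrimerPair]:
    """All primer pairs on a template segment satisfying the design predicates.

    ``offset`` places the segment within its transcript so primer ``start``
    coordinates are transcript coordinates.  Output order is deterministic:
    (forward start, forward length, reverse-site start, reverse length).
    """
    params = params or DesignParams()
    arrays = _pair_arrays(segment_seq, params)
    if arrays is None:
        return []
    s, e, l, tm, gc = arrays["windows"]
    order = np.lexsort(
        (l[arrays["b"]], s[arrays["b"]], l[arrays["a"]], s[arrays["a"]])
    )
    return [_materialize(segment_seq, offset, arrays, int(i), params) for i in order]


def iter_ranked_pairs(segment_seq: str, params: DesignParams | None = None,
                      offset: int = 0) -> Iterator[PrimerPair]:
    """Yield candidate pairs lazily in exact (penalty, start, seqs) order."""
    params = params or DesignParams()
    arrays = _pair_arrays(segment_seq, params)
    if arrays is None:
        return
    order = np.argsort(arrays["penalty"], kind="stable")
    pen = arrays["penalty"]
    buffer: list[PrimerPair] = []
    current = None
    for i in order:
        p = pen[i]
        if current is not None and p != current:
            buffer.sort(key=lambda pp: pp.key)
            yield from buffer
            buffer = []
        current = p
        buffer.append(_materialize(segment_seq, offset, arrays, int(i), params))
    buffer.sort(key=lambda pp: pp.key)
    yield from buffer


def merge_ranked(streams: list[Iterator[PrimerPair]]) -> Iterator[PrimerPair]:
    """Merge per-segment ranked streams into one global penalty order."""
    return heapq.merge(*streams, key=lambda pp: pp.key)


# ---------------------------------------------------------------------------
# selection


@dataclass
class SelectionResult:
    pairs: list[PrimerPair]
    shortfall: bool
    examined: int = 0


def _overlap_fraction(a: PrimerPair, b: PrimerPair) -> float:
    inter = min(a.amplicon_end, b.amplicon_end) - max(a.amplicon_start, b.amplicon_start)
    if inter <= 0:
        return 0.0
    return inter / min(a.product_length, b.product_length)


def select_top_pairs(
    candidates: Iterable[PrimerPair],
    k: int,
    specificity_verdicts: Callable[[PrimerPair], object] | dict,
    max_classified: int | None = None,
) -> SelectionResult:
    """Pick up to ``k`` gene-specific pairs with amplicon diversity.

    ``candidates`` must be ordered by (penalty, amplicon start, sequences);
    lists are re-sorted defensively, iterators are trusted.  The verdict
    source is a callable (or mapping keyed by (fwd_seq, rev_seq)) returning
    an object with a ``gene_specific`` attribute.  Greedy acceptance requires
    each new amplicon to overlap every accepted amplicon by < 50% of the
    shorter one; if fewer than k survive, the diversity rule is dropped and
    the best remaining specific pairs fill up to k.  ``max_classified`` caps
    how many candidates are sent to the specificity screen.
    """
    if isinstance(specificity_verdicts, dict):
        verdict_map = specificity_verdicts
        verdict = lambda p: verdict_map[(p.forward.seq, p.reverse.seq)]  # noqa: E731
    else:
        verdict = specificity_verdicts
    if isinstance(candidates, list):
        candidates = iter(sorted(candidates, key=lambda pp: pp.key))
    accepted: list[PrimerPair] = []
    reserve: list[PrimerPair] = []
    examined = 0
    for pair in candidates:
        if len(accepted) >= k:
            break
        if max_classified is not None and examined >= max_classified:
            break
        examined += 1
        v = verdict(pair)
        if not getattr(v, "gene_specific", False):
            continue
        if all(_overlap_fraction(pair, acc) < 0.5 for acc in accepted):
            accepted.append(pair)
        else:
            reserve.append(pair)
    while len(accepted) < k and reserve:
        accepted.append(reserve.pop(0))
    return SelectionResult(pairs=accepted, shortfall=len(accepted) < k,
                           examined=examined)


def _revcomp(seq: str) -> str:
    from .transcriptome import revcomp

    return revcomp(seq)
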