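"""Sequence-context analyses around editing sites.

Three views of how local sequence shapes editing:

* motif information content (LOGO-style bit scores) of the +/-k flanks,
  stratified by editing level;
* enrichment of +/-1 flank mismatches at editing-status-discordant
  homologous adenines (R with a chi-squared contingency test,
  Bonferroni-corrected over the mismatch types tested);
* the correlation between |editing-level difference| at conserved sites
  and the number of mismatches in a variable-sized window centered on
  the site, whose argmax estimates the span of context that the editing
  machinery reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (
    A, E, GAP, N as N_STATE,
    NUCLEOTIDES,
    EditingSite,
    OrthoAlignment,
    Transcript,
)
from .stats import StatEstimate

logger = logging.getLogger(__name__)

#: ordered non-identical nucleotide pairs per flank position (Bonferroni m)
N_MISMATCH_TYPES = 12


@dataclass
class MotifProfile:
    """Per-position nucleotide frequencies and information content (bits)."""

    offsets: list[int]
    frequencies: pd.DataFrame  # index: offset, columns: A C G T
    bits: pd.Series  # information content per offset, 2 - H
    el_range: tuple[float, float] | None = None
    n_sites: int = 0


@dataclass
class ContextCounts:
    """Flank-mismatch tallies at status-discordant and concordant pairs.

    ``mismatches[side][(n1, n2)]`` counts columns where the species with
    the edited (resp. unedited) adenine carries ``n1`` and the partner
    ``n2 != n1`` at flank ``side`` (+1 or -1).  Totals are the numbers
    of homologous E-A and A-A columns considered.
    """

    ea_mismatches: dict[int, dict[tuple[str, str], int]]
    aa_mismatches: dict[int, dict[tuple[str, str], int]]
    n_ea: int = 0
    n_aa: int = 0


def motif_bitscore(
    sites: Iterable[EditingSite],
    transcripts: Mapping[str, Transcript],
    el_range: tuple[float, float] | None = None,
    k: int = 5,
) -> MotifProfile:
    """Nucleotide frequencies and 2 - H(freq) bits at offsets -k..+k.

    Sites lacking a full flank are trimmed from the affected offsets
    (logged).  No small-sample correction is applied.
    """
    offsets = list(range(-k, k + 1))
    counts = {o: {b: 0 for b in NUCLEOTIDES} for o in offsets}
    n_used = n_trimmed = 0
    for s in sites:
        if el_range is not None and not (el_range[0] <= s.editing_level < el_range[1]):
            continue
        tr = transcripts.get(s.transcript_id)
        if tr is None:
            continue
        n_used += 1
        for o in offsets:
            p = s.pos + o
            if 0 <= p < len(tr.cds) and tr.cds[p] in NUCLEOTIDES:
                counts[o][tr.cds[p]] += 1
            else:
                n_trimmed += 1
    if n_used == 0:
        raise ValueError("no editing sites in the requested stratum")
    if n_trimmed:
        logger.info("motif: %d flank cells trimmed at transcript ends", n_trimmed)
    freq_rows, bit_vals = {}, {}
    for o in offsets:
        tot = sum(counts[o].values())
        if tot == 0:
            freq_rows[o] = {b: np.nan for b in NUCLEOTIDES}
            bit_vals[o] = np.nan
            continue
        freqs = {b: counts[o][b] / tot for b in NUCLEOTIDES}
        fs = np.array([v for v in freqs.values() if v > 0])
        bit_vals[o] = 2.0 + float(np.sum(fs * np.log2(fs)))
        freq_rows[o] = freqs
    return MotifProfile(
        offsets=offsets,
        frequencies=pd.DataFrame.from_dict(freq_rows, orient="index"),
        bits=pd.Series(bit_vals),
        el_range=el_range,
        n_sites=n_used,
    )


def context_counts(
    alignments: Iterable[OrthoAlignment],
    sp1: str,
    sp2: str,
    transcripts: Mapping[str, Mapping[str, Transcript]],
    symmetrize: bool = True,
) -> ContextCounts:
    """Tally +/-1 flank mismatches at E-A (discordant) and A-A columns.

    The first member of each mismatch pair is the nucleotide in the
    edited species (for E-A columns) or in ``sp1`` (for A-A columns,
    symmetrized by counting both orientations when ``symmetrize``).
    Flanks are read from each species' own transcript sequence via the
    back-map; columns whose flank falls off the transcript or is
    ambiguous are excluded from that side's tally (the column still
    counts toward the totals, which the invariant Sum <= total reflects).
    """
    ea = {side: {} for side in (+1, -1)}
    aa = {side: {} for side in (+1, -1)}
    n_ea = n_aa = 0

    def flank(tr: Transcript, pos: int, side: int) -> str | None:
        p = pos + side
        if tr is None or not 0 <= p < len(tr.cds):
            return None
        b = tr.cds[p]
        return b if b in NUCLEOTIDES else None

    for aln in alignments:
        s1, s2 = aln.states[sp1], aln.states[sp2]
        tr1 = transcripts.get(sp1, {}).get(aln.transcript_ids.get(sp1))
        tr2 = transcripts.get(sp2, {}).get(aln.transcript_ids.get(sp2))
        bm1, bm2 = aln.backmap[sp1], aln.backmap[sp2]
        discord = ((s1 == E) & (s2 == A)) | ((s1 == A) & (s2 == E))
        concord = (s1 == A) & (s2 == A)
        for col in np.nonzero(discord | concord)[0]:
            if discord[col]:
                n_ea += 1
                if s1[col] == E:
                    tre, pe, tru, pu = tr1, bm1[col], tr2, bm2[col]
                else:
                    tre, pe, tru, pu = tr2, bm2[col], tr1, bm1[col]
                for side in (+1, -1):
                    b1, b2 = flank(tre, pe, side), flank(tru, pu, side)
                    if b1 and b2 and b1 != b2:
                        ea[side][(b1, b2)] = ea[side].get((b1, b2), 0) + 1
            else:
                n_aa += 1
                for side in (+1, -1):
                    b1, b2 = flank(tr1, bm1[col], side), flank(tr2, bm2[col], side)
                    if b1 and b2 and b1 != b2:
                        aa[side][(b1, b2)] = aa[side].get((b1, b2), 0) + 1
                        if symmetrize:
                            aa[side][(b2, b1)] = aa[side].get((b2, b1), 0) + 1
    if symmetrize:
        # both orientations counted: totals double accordingly
        n_aa *= 2
    return ContextCounts(ea_mismatches=ea, aa_mismatches=aa, n_ea=n_ea, n_aa=n_aa)


def context_mismatch_R(
    counts: ContextCounts,
    n1: str,
    n2: str,
    side: int = +1,
    m: int = N_MISMATCH_TYPES,
) -> StatEstimate:
    """R^+/-1 for one mismatch type with chi-squared + Bonferroni p.

    R = [#(EN1, AN2)/#(E,A)] / [#(AN1, AN2)/#(A,A)].  The p-value comes
    from the chi-squared test on the 2x2 matrix [[#(EN1,AN2), #(AN1,AN2)],
    [#(E,A), #(A,A)]], Bonferroni-scaled by ``m`` (the number of ordered
    mismatch types tested per flank position, reported in the output).
    """
    c_ea = counts.ea_mismatches[side].get((n1, n2), 0)
    c_aa = counts.aa_mismatches[side].get((n1, n2), 0)
    name = f"R_ctx_{n1}{n2}_{'+1' if side > 0 else '-1'}"
    if counts.n_ea == 0 or counts.n_aa == 0 or c_aa == 0:
        return StatEstimate(name, float("nan"), undefined=True,
                            n_numerator_events=c_ea, n_denominator_events=c_aa,
                            extras={"bonferroni_m": m})
    value = (c_ea / counts.n_ea) / (c_aa / counts.n_aa)
    table = np.array([[c_ea, c_aa], [counts.n_ea, counts.n_aa]], dtype=float)
    if c_ea == 0:
        p_raw = 1.0
    else:
        chi2, p_raw, _, _ = sps.chi2_contingency(table)
    p = min(1.0, m * p_raw)
    return StatEstimate(name, float(value), p_value=float(p),
                        n_numerator_events=c_ea, n_denominator_events=c_aa,
                        extras={"p_raw": float(p_raw), "bonferroni_m": m,
                                "n_EA": counts.n_ea, "n_AA": counts.n_aa})


def window_el_correlation(
    alignments: Iterable[OrthoAlignment],
    sp1: str,
    sp2: str,
    window_sizes: Sequence[int] = tuple(range(20, 201, 10)),
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, int | None]:
    """Correlation of |ΔEL| at conserved sites with windowed mismatch counts.

    For every window size W the Pearson r between the absolute
    editing-level difference of conserved editing sites (edited in both
    species) and the number of nucleotide mismatches within the W-nt
    window centered on the site (the focal position and gap columns
    excluded; windows clipped at alignment ends).  Returns the full
    (window, r, n_pairs) curve and the argmax window (None when r is
    undefined everywhere).
    """
    alignments = list(alignments)
    ces = []  # (aln index, column)
    for i, aln in enumerate(alignments):
        both = (aln.states[sp1] == E) & (aln.states[sp2] == E)
        for col in np.nonzero(both)[0]:
            ces.append((i, int(col)))
    if len(ces) < min_pairs:
        raise ValueError(f"fewer than {min_pairs} conserved editing-site pairs")

    dels = np.array(
        [abs(alignments[i].els[sp1][c] - alignments[i].els[sp2][c]) for i, c in ces]
    )
    # per-alignment mismatch indicator and prefix sums (nucleotide layer)
    prefix = []
    for aln in alignments:
        n1, n2 = aln.nucleotide_states(sp1), aln.nucleotide_states(sp2)
        ok = ~np.isin(n1, (GAP, N_STATE)) & ~np.isin(n2, (GAP, N_STATE))
        mism = ((n1 != n2) & ok).astype(np.int64)
        prefix.append((mism, np.concatenate([[0], np.cumsum(mism)])))

    rows = []
    best = (None, -np.inf)
    for w in window_sizes:
        half = w // 2
        m = np.empty(len(ces))
        for j, (i, c) in enumerate(ces):
            mism, cs = prefix[i]
            lo, hi = max(0, c - half), min(len(mism), c + half + 1)
            m[j] = cs[hi] - cs[lo] - mism[c]
        if np.std(m) == 0 or np.std(dels) == 0:
            rows.append({"window": w, "r": np.nan, "n_pairs": len(ces)})
            continue
        r = float(np.corrcoef(dels, m)[0, 1])
        rows.append({"window": w, "r": r, "n_pairs": len(ces)})
        if r > best[1]:
            best = (int(w), r)
    curve = pd.DataFrame(rows)
    return curve, best[0]
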