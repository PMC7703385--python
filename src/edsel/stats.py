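"""Substitution-bias statistics at editing sites: R, Q and editing-aware dN/dS.

All statistics compare edited adenines (E) with unedited adenines (A):

* undirected, extant species pair:  R_N = p(E,N) / p(A,N)
* ancestor -> descendant:           R_->N = p(E->N) / p(A->N)
* descendant <- ancestor N:         R_N-> = p*(N->E) / p*(N->A), with the
  density normalization p*(N->E) = p(N->E) / (#E / (#E + #A)) and its
  analogue for A
* Q_->* = R_->G / R_->Y  and  Q_*-> = R_G-> / R_Y->, with C and T counts
  pooled into Y before any ratio is formed.

Every probability is per opportunity: p(E->N) = counts(E->N) / rowsum(E),
with the diagonal (no-change) events included in the row sum.  Confidence
intervals come from binomial resampling of each constituent count at its
observed frequency (percentile method); statistics whose denominator
count is zero are emitted as undefined, never silently pseudocounted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ancestry import SubstitutionMatrix, build_substitution_matrix
from .io import (
    GAP, N as N_STATE,
    STATE_CHARS,
    OrthoAlignment,
    SENSE_CODONS,
    SpeciesTriplet,
    Synonymy,
    Transcript,
    position_synonymy_arrays,
    translate_codon,
)

logger = logging.getLogger(__name__)

DEFAULT_REPS = 100_000


@dataclass
class StatEstimate:
    """A named ratio statistic with resampling CI and counts."""

    name: str
    value: float
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    n_numerator_events: int = 0
    n_denominator_events: int = 0
    el_bin: tuple[float, float] | None = None
    undefined: bool = False
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "statistic": self.name,
            "el_bin": "" if self.el_bin is None else f"{self.el_bin[0]:g}-{self.el_bin[1]:g}",
            "value": self.value,
            "ci_low": None if self.ci95 is None else self.ci95[0],
            "ci_high": None if self.ci95 is None else self.ci95[1],
            "p": self.p_value,
            "n_num": self.n_numerator_events,
            "n_den": self.n_denominator_events,
            "undefined": self.undefined,
        }


# ---------------------------------------------------------------------------
# Binomial resampling
# ---------------------------------------------------------------------------


def _resample(counts, ns, statistic_fn, reps, rng):
    counts = np.atleast_1d(np.asarray(counts, dtype=np.int64))
    ns = np.atleast_1d(np.asarray(ns, dtype=np.int64))
    draws = rng.binomial(ns, counts / ns, size=(reps, len(counts)))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.asarray(statistic_fn(draws), dtype=float)
    return vals


def binomial_resample_ci(
    count,
    n,
    statistic_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> tuple[float, float]:
    """95% percentile CI of a statistic of binomial counts.

    ``count`` and ``n`` may be scalars or parallel sequences; each
    constituent count is resampled from Binomial(n_i, count_i/n_i) and
    the statistic recomputed ``reps`` times.  ``statistic_fn`` receives
    the resampled counts as a (reps, k) array and must return one value
    per replicate; the default is the plain proportion (k = 1).
    Non-finite replicate values (zero resampled denominators) are
    dropped before taking percentiles.
    """
    ns = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if (ns <= 0).any():
        raise ValueError("n must be positive")
    cs = np.atleast_1d(np.asarray(count, dtype=np.int64))
    if ((cs < 0) | (cs > ns)).any():
        raise ValueError("need 0 <= count <= n")
    if statistic_fn is None:
        statistic_fn = lambda d: d[:, 0] / ns[0]
    rng = np.random.default_rng(seed)
    vals = _resample(cs, ns, statistic_fn, reps, rng)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return (float(lo), float(hi))


def _ci_and_p(counts, ns, fn, reps, seed, null=1.0):
    """CI plus a two-sided resampling p-value against ``null``."""
    rng = np.random.default_rng(seed)
    vals = _resample(counts, ns, fn, reps, rng)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return None, None
    lo, hi = np.percentile(finite, [2.5, 97.5])
    p = 2.0 * min(np.mean(finite <= null), np.mean(finite >= null))
    return (float(lo), float(hi)), float(min(1.0, max(p, 1.0 / len(finite))))


# ---------------------------------------------------------------------------
# Matrix-based directed statistics
# ---------------------------------------------------------------------------

_IDX = {ch: i for i, ch in enumerate(("A", "E", "C", "G", "T"))}


def _counts_of(matrix: SubstitutionMatrix, syn_class: Synonymy | None) -> np.ndarray:
    if syn_class is None:
        return matrix.counts
    if not matrix.by_class:
        raise ValueError("matrix was built without synonymy stratification")
    return matrix.by_class[syn_class]


def _row(counts: np.ndarray, anc: str) -> tuple[Callable[[str], int], int]:
    """Event getter and opportunity count for an ancestor row ('Y' pools C,T)."""
    rows = [_IDX[a] for a in (("C", "T") if anc == "Y" else (anc,))]

    def events(desc: str) -> int:
        cols = [_IDX[d] for d in (("C", "T") if desc == "Y" else (desc,))]
        return int(sum(counts[r, c] for r in rows for c in cols))

    nn = int(sum(counts[r].sum() for r in rows))
    return events, nn


def directed_R_to(
    matrix: SubstitutionMatrix,
    N: str = "G",
    syn_class: Synonymy | None = None,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> StatEstimate:
    """R_->N: substitution probability of edited vs unedited ancestral adenines."""
    counts = _counts_of(matrix, syn_class)
    e_events, n_e = _row(counts, "E")
    a_events, n_a = _row(counts, "A")
    c_e, c_a = e_events(N), a_events(N)
    name = f"R_to_{N}" + (f"_{syn_class.value}" if syn_class else "")
    if n_e == 0 or n_a == 0 or c_a == 0:
        return StatEstimate(name, float("nan"), undefined=True,
                            n_numerator_events=c_e, n_denominator_events=c_a)
    value = (c_e / n_e) / (c_a / n_a)
    ci, p = _ci_and_p(
        [c_e, c_a], [n_e, n_a],
        lambda d: (d[:, 0] / n_e) / (d[:, 1] / n_a), reps, seed,
    )
    return StatEstimate(name, float(value), ci, p, c_e, c_a)


def directed_R_from(
    matrix: SubstitutionMatrix,
    N: str = "G",
    n_E: int | None = None,
    n_A: int | None = None,
    syn_class: Synonymy | None = None,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> StatEstimate:
    """R_N->: density-normalized preference of ancestral N to become E vs A.

    ``n_E``/``n_A`` are the transcriptome-wide edited/unedited adenine
    counts of the focal species; they default to the focal E/A column
    counts of the matrix itself.
    """
    counts = _counts_of(matrix, syn_class)
    n_E = matrix.n_focal_E if n_E is None else n_E
    n_A = matrix.n_focal_A if n_A is None else n_A
    events, n_n = _row(counts, N)
    c_ne, c_na = events("E"), events("A")
    name = f"R_{N}_from" + (f"_{syn_class.value}" if syn_class else "")
    if n_E == 0 or n_n == 0 or c_na == 0:
        return StatEstimate(name, float("nan"), undefined=True,
                            n_numerator_events=c_ne, n_denominator_events=c_na)
    dens = n_A / n_E  # p*-normalization factor: (#A/(#E+#A)) / (#E/(#E+#A))
    value = (c_ne / c_na) * dens
    ci, p = _ci_and_p(
        [c_ne, c_na], [n_n, n_n],
        lambda d: (d[:, 0] / d[:, 1]) * dens, reps, seed,
    )
    return StatEstimate(name, float(value), ci, p, c_ne, c_na,
                        extras={"n_E": n_E, "n_A": n_A})


def q_forward(
    matrix: SubstitutionMatrix,
    syn_class: Synonymy | None = None,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> StatEstimate:
    """Q_->* = R_->G / R_->Y: guanine preference of edited-adenine substitutions."""
    counts = _counts_of(matrix, syn_class)
    e_events, n_e = _row(counts, "E")
    a_events, n_a = _row(counts, "A")
    c = [e_events("G"), e_events("Y"), a_events("G"), a_events("Y")]
    name = "Q_forward" + (f"_{syn_class.value}" if syn_class else "")
    if n_e == 0 or n_a == 0 or 0 in (c[1], c[2]):
        return StatEstimate(name, float("nan"), undefined=True,
                            n_numerator_events=c[0], n_denominator_events=c[1])
    # opportunity counts cancel: (cEG/cEY) / (cAG/cAY)
    value = (c[0] / c[1]) / (c[2] / c[3])
    ci, p = _ci_and_p(
        c, [n_e, n_e, n_a, n_a],
        lambda d: (d[:, 0] / d[:, 1]) / (d[:, 2] / d[:, 3]), reps, seed,
    )
    return StatEstimate(name, float(value), ci, p, c[0], c[1],
                        extras={"counts": c, "n_E_row": n_e, "n_A_row": n_a})


def q_backward(
    matrix: SubstitutionMatrix,
    n_E: int | None = None,
    n_A: int | None = None,
    syn_class: Synonymy | None = None,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> StatEstimate:
    """Q_*-> = R_G-> / R_Y->: preference of guanines to become edited adenines."""
    counts = _counts_of(matrix, syn_class)
    g_events, n_g = _row(counts, "G")
    y_events, n_y = _row(counts, "Y")
    c = [g_events("E"), g_events("A"), y_events("E"), y_events("A")]
    name = "Q_backward" + (f"_{syn_class.value}" if syn_class else "")
    if n_g == 0 or n_y == 0 or 0 in (c[1], c[2]):
        return StatEstimate(name, float("nan"), undefined=True,
                            n_numerator_events=c[0], n_denominator_events=c[2])
    # the density normalization cancels in the ratio of the two R_N->
    value = (c[0] / c[1]) / (c[2] / c[3])
    ci, p = _ci_and_p(
        c, [n_g, n_g, n_y, n_y],
        lambda d: (d[:, 0] / d[:, 1]) / (d[:, 2] / d[:, 3]), reps, seed,
    )
    return StatEstimate(name, float(value), ci, p, c[0], c[2],
                        extras={"counts": c})


def r_syn_nonsyn_split(
    matrix: SubstitutionMatrix,
    direction: str = "to",
    N: str = "G",
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
    **kwargs,
) -> dict[Synonymy, StatEstimate]:
    """R computed separately for synonymous and nonsynonymous site classes.

    ``direction`` is ``"to"`` (edited/unedited ancestral adenine to N) or
    ``"from"`` (ancestral N to edited/unedited adenine, with N restricted
    to positions where A and G encode the same / different amino acid).
    NONCODING columns are excluded.
    """
    fn = directed_R_to if direction == "to" else directed_R_from
    return {
        cl: fn(matrix, N=N, syn_class=cl, reps=reps, seed=seed, **kwargs)
        for cl in (Synonymy.SYN, Synonymy.NONSYN)
    }


# ---------------------------------------------------------------------------
# Extant-pair (undirected) statistics
# ---------------------------------------------------------------------------


def pair_table(
    alignments: Iterable[OrthoAlignment],
    sp1: str,
    sp2: str,
    transcripts: Mapping[str, Mapping[str, Transcript]] | None = None,
) -> pd.DataFrame:
    """Column table for an extant species pair.

    One row per alignment column with state characters, editing levels
    and (when ``transcripts`` carries both species) the forced-A
    synonymy class and four-fold-degenerate flag of each species' own
    position.
    """
    frames = []
    chars = np.array(list(STATE_CHARS))
    for aln in alignments:
        d = {
            "state1": chars[aln.states[sp1]],
            "state2": chars[aln.states[sp2]],
            "el1": aln.els[sp1],
            "el2": aln.els[sp2],
        }
        for tag, sp in (("1", sp1), ("2", sp2)):
            syn = np.full(aln.n_columns, -1, dtype=np.int8)
            four = np.zeros(aln.n_columns, dtype=bool)
            if transcripts is not None:
                tr = transcripts.get(sp, {}).get(aln.transcript_ids.get(sp))
                if tr is not None:
                    psyn, pfour = position_synonymy_arrays(tr)
                    pos = aln.backmap[sp]
                    ng = pos >= 0
                    syn[ng] = psyn[pos[ng]]
                    four[ng] = pfour[pos[ng]]
            d[f"syn{tag}"] = syn
            d[f"four{tag}"] = four
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def mismatch_R(
    pairs: pd.DataFrame,
    N: str = "G",
    el_range: tuple[float, float] | None = None,
    direction: int = 1,
    syn_class: Synonymy | None = None,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> StatEstimate:
    """Undirected R_N = p(E,N) / p(A,N) for an extant pair.

    ``direction`` selects which species carries the E/A state (1 or 2);
    the partner species supplies the mismatched nucleotide.  Denominators
    are aligned E (resp. A) columns whose partner state is unambiguous.
    """
    a, b = ("1", "2") if direction == 1 else ("2", "1")
    st_a = pairs[f"state{a}"].to_numpy()
    st_b = pairs[f"state{b}"].to_numpy()
    el_a = pairs[f"el{a}"].to_numpy()
    partner_ok = ~np.isin(st_b, ("-", "N"))
    is_e = (st_a == "E") & partner_ok
    is_a = (st_a == "A") & partner_ok
    if el_range is not None:
        lo, hi = el_range
        is_e &= (el_a >= lo) & (el_a < hi)
    if syn_class is not None:
        want = {Synonymy.SYN: 1, Synonymy.NONSYN: 0, Synonymy.NONCODING: -1}[syn_class]
        cls = pairs[f"syn{a}"].to_numpy()
        is_e &= cls == want
        is_a &= cls == want
    targets = ("C", "T") if N == "Y" else (N,)
    hit = np.isin(st_b, targets)
    c_e, n_e = int((is_e & hit).sum()), int(is_e.sum())
    c_a, n_a = int((is_a & hit).sum()), int(is_a.sum())
    name = f"R_{N}"
    if n_e == 0 or n_a == 0 or c_a == 0:
        return StatEstimate(name, float("nan"), undefined=True, el_bin=el_range,
                            n_numerator_events=c_e, n_denominator_events=c_a)
    value = (c_e / n_e) / (c_a / n_a)
    ci, p = _ci_and_p(
        [c_e, c_a], [n_e, n_a],
        lambda d: (d[:, 0] / n_e) / (d[:, 1] / n_a), reps, seed,
    )
    return StatEstimate(name, float(value), ci, p, c_e, c_a, el_bin=el_range)


# ---------------------------------------------------------------------------
# Codon weights and editing-aware dN/dS
# ---------------------------------------------------------------------------


@dataclass
class CodonWeights:
    """Codon frequencies and A->G mutational-opportunity normalizers.

    ``k_non[c]``/``k_syn[c]`` count the nonsynonymous/synonymous A->G
    changes available in codon ``c`` (their sum is the number of A's in
    the codon); ``xi_non``/``xi_syn`` are reciprocals of the
    frequency-weighted sums, converting raw substitution proportions to
    comparable per-opportunity rates.
    """

    f: dict[str, float]
    k_non: dict[str, int]
    k_syn: dict[str, int]
    xi_non: float
    xi_syn: float


def codon_weights(transcripts: Mapping[str, Transcript]) -> CodonWeights:
    counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for tr in transcripts.values():
        for ci in range(tr.n_codons):
            codon = tr.codon(ci)
            if codon in counts:
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complete sense codons in transcripts")
    f = {c: n / total for c, n in counts.items()}
    k_non, k_syn = {}, {}
    for codon in SENSE_CODONS:
        non = syn = 0
        for w, base in enumerate(codon):
            if base != "A":
                continue
            mutated = codon[:w] + "G" + codon[w + 1 :]
            if translate_codon(mutated) == translate_codon(codon):
                syn += 1
            else:
                non += 1
        k_non[codon], k_syn[codon] = non, syn
    s_non = sum(f[c] * k_non[c] for c in SENSE_CODONS)
    s_syn = sum(f[c] * k_syn[c] for c in SENSE_CODONS)
    if s_non == 0 or s_syn == 0:
        raise ValueError("degenerate codon usage: zero A->G opportunity mass")
    return CodonWeights(f=f, k_non=k_non, k_syn=k_syn,
                        xi_non=1.0 / s_non, xi_syn=1.0 / s_syn)


def el_bins(bin_width: float = 0.10) -> list[tuple[float, float]]:
    k = round(1.0 / bin_width)
    if abs(k * bin_width - 1.0) > 1e-9:
        raise ValueError("bin width must divide 1 evenly")
    edges = np.round(np.linspace(0.0, 1.0, k + 1), 12)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(k)]


def _bin_mask(el: np.ndarray, bin_: tuple[float, float]) -> np.ndarray:
    lo, hi = bin_
    upper = el <= hi if hi >= 1.0 else el < hi  # last bin closed at 1.0
    return (el >= lo) & upper


def pearson_f_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its F-statistic p-value (F(1, n-2) = t^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    df = len(x) - 2
    f = r * r * df / (1.0 - r * r)
    return r, float(sps.f.sf(f, 1, df))


def dnds_edited_vs_unedited(
    pairs: pd.DataFrame,
    N_target: str = "G",
    bin_width: float = 0.10,
    direction: int = 1,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> tuple[list[StatEstimate], float, float]:
    """[dN(E->N)/dS(E->N)] / [dN(A->N)/dS(A->N)] per 10% editing-level bin.

    dN uses nonsynonymous sites in all codons; dS uses synonymous sites
    restricted to third positions of four-fold degenerate codon families
    (including the four-fold subfamilies of the six-fold families).
    Returns the per-bin estimates plus the Pearson correlation of the
    statistic against the bin midpoint and its F-test p-value.
    """
    a, b = ("1", "2") if direction == 1 else ("2", "1")
    st_a = pairs[f"state{a}"].to_numpy()
    st_b = pairs[f"state{b}"].to_numpy()
    el_a = pairs[f"el{a}"].to_numpy()
    cls = pairs[f"syn{a}"].to_numpy()
    four = pairs[f"four{a}"].to_numpy()
    partner_ok = ~np.isin(st_b, ("-", "N"))
    targets = ("C", "T") if N_target == "Y" else (N_target,)
    hit = np.isin(st_b, targets)

    def cn(mask):
        return int((mask & hit).sum()), int(mask.sum())

    non_mask = partner_ok & (cls == 0)
    syn_mask = partner_ok & (cls == 1) & four
    dn_a = cn((st_a == "A") & non_mask)
    ds_a = cn((st_a == "A") & syn_mask)

    out: list[StatEstimate] = []
    mids, vals = [], []
    for bin_ in el_bins(bin_width):
        in_bin = (st_a == "E") & _bin_mask(el_a, bin_)
        dn_e = cn(in_bin & non_mask)
        ds_e = cn(in_bin & syn_mask)
        name = f"dNdS_E_vs_A_{N_target}"
        counts = [dn_e[0], ds_e[0], dn_a[0], ds_a[0]]
        ns = [dn_e[1], ds_e[1], dn_a[1], ds_a[1]]
        if 0 in ns or 0 in (ds_e[0], dn_a[0], ds_a[0]):
            if dn_e[1] > 0:  # populated bin but undefined ratio
                out.append(StatEstimate(name, float("nan"), el_bin=bin_,
                                        undefined=True,
                                        n_numerator_events=dn_e[0],
                                        n_denominator_events=ds_e[0]))
            continue
        value = (dn_e[0] / dn_e[1]) / (ds_e[0] / ds_e[1])
        value /= (dn_a[0] / dn_a[1]) / (ds_a[0] / ds_a[1])
        ci, p = _ci_and_p(
            counts, ns,
            lambda d: ((d[:, 0] / ns[0]) / (d[:, 1] / ns[1]))
            / ((d[:, 2] / ns[2]) / (d[:, 3] / ns[3])),
            reps, seed,
        )
        est = StatEstimate(name, float(value), ci, p, dn_e[0], ds_e[0], el_bin=bin_)
        out.append(est)
        mids.append((bin_[0] + bin_[1]) / 2)
        vals.append(value)
    r, p_f = pearson_f_test(mids, vals)
    return out, r, p_f


def dnds_positive_selection(
    alignments: Iterable[OrthoAlignment],
    triplet: SpeciesTriplet,
    transcripts: Mapping[str, Transcript],
    weights: CodonWeights,
    el_thresholds: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> list[StatEstimate]:
    """dN(E->G)/dS(A->G) = [p(E_non->G)/p(A_syn->G)] * (xi_non/xi_syn).

    Nonsynonymous substitutions are taken at edited adenines and
    synonymous ones at unedited adenines; values above 1 indicate
    positive selection on the E->G transition.  Swept over editing-level
    thresholds (edited sites with EL below the threshold are excluded
    from the matrix).
    """
    alignments = list(alignments)
    xi_ratio = weights.xi_non / weights.xi_syn
    out = []
    for thr in el_thresholds:
        mat = build_substitution_matrix(
            alignments, triplet, transcripts=transcripts, el_min=thr
        )
        non = mat.by_class[Synonymy.NONSYN]
        syn = mat.by_class[Synonymy.SYN]
        c_e, n_e = int(non[_IDX["E"], _IDX["G"]]), int(non[_IDX["E"]].sum())
        c_a, n_a = int(syn[_IDX["A"], _IDX["G"]]), int(syn[_IDX["A"]].sum())
        name = "dNdS_positive"
        if n_e == 0 or n_a == 0 or c_a == 0:
            out.append(StatEstimate(name, float("nan"), undefined=True,
                                    el_bin=(thr, 1.0),
                                    n_numerator_events=c_e,
                                    n_denominator_events=c_a))
            continue
        value = (c_e / n_e) / (c_a / n_a) * xi_ratio
        ci, p = _ci_and_p(
            [c_e, c_a], [n_e, n_a],
            lambda d: (d[:, 0] / n_e) / (d[:, 1] / n_a) * xi_ratio, reps, seed,
        )
        out.append(StatEstimate(name, float(value), ci, p, c_e, c_a,
                                el_bin=(thr, 1.0),
                                extras={"xi_non": weights.xi_non,
                                        "xi_syn": weights.xi_syn}))
    return out


def el_binned(
    stat_for_bin: Callable[[tuple[float, float]], StatEstimate | None],
    bin_width: float = 0.10,
) -> tuple[list[StatEstimate], float, float]:
    """Apply a per-bin statistic over half-open 10% EL bins.

    Returns the defined estimates plus Pearson r (statistic vs bin
    midpoint) and the F-test p-value across bins; r is NaN (flagged by
    the caller) when fewer than three bins are defined or the statistic
    is constant.
    """
    out, mids, vals = [], [], []
    for bin_ in el_bins(bin_width):
        est = stat_for_bin(bin_)
        if est is None:
            continue
        out.append(est)
        if not est.undefined and np.isfinite(est.value):
            mids.append((bin_[0] + bin_[1]) / 2)
            vals.append(est.value)
    r, p = pearson_f_test(mids, vals)
    return out, r, p


def estimates_to_frame(estimates: Iterable[StatEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.as_row() for e in estimates])
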