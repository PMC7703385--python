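"""RNA secondary-structure potential from dinucleotide-preserving shuffles.

A window's structural potential is standardized folding energy,
Z = (E - mu) / sigma, where mu and sigma describe the energy
distribution of shuffles that preserve the window's length and exact
dinucleotide composition (Altschul-Erickson Euler-path shuffles).
Windows of length 20-350 are slid over a transcript; each position is
assigned the minimum Z over segments covering it when that minimum is
below -2, otherwise null.

The default energy function is a deliberately simple stacking
approximation (best single helical stem; see ``stacking_energy``); any
callable mapping a sequence to a free energy can be plugged in, and the
energy-model id is stamped into every profile.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .io import NUCLEOTIDES, Transcript

logger = logging.getLogger(__name__)

MIN_WINDOW = 20
MAX_WINDOW = 350
Z_THRESHOLD = -2.0

#: per-pair stack weights (kcal/mol-like); a stem of L pairs scores the sum
#: of its pair weights, stems of a single pair score 0 (no stacking).
PAIR_STACK_WEIGHTS = {
    ("G", "C"): -3.4, ("C", "G"): -3.4,
    ("A", "T"): -2.2, ("T", "A"): -2.2,
    ("G", "T"): -1.2, ("T", "G"): -1.2,
}
MIN_LOOP = 3


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul & Erickson Euler-path method)
# ---------------------------------------------------------------------------


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        out[d] = out.get(d, 0) + 1
    return out


def dinucleotide_shuffle(
    seq: str, n_shuffles: int, seed: int | None = None
) -> list[str]:
    """Shuffles preserving length, first nucleotide and the exact
    dinucleotide multiset (Euler-path construction).

    Deterministic under ``seed``.
    """
    if len(seq) < 3:
        raise ValueError("sequence too short to shuffle")
    if any(b not in NUCLEOTIDES for b in seq):
        raise ValueError("dinucleotide shuffle requires an ACGT-only sequence")
    rng = random.Random(seed)
    edges: dict[str, list[str]] = {}
    for i in range(len(seq) - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    first, last = seq[0], seq[-1]
    vertices = list(edges)

    def sample_last_edges() -> dict[str, str] | None:
        # pick one terminal edge per non-terminal vertex; valid iff the
        # chosen edges form a tree converging on the last vertex
        chosen = {}
        for v in vertices:
            if v == last:
                continue
            chosen[v] = rng.choice(edges[v])
        for v in chosen:
            seen, cur = set(), v
            while cur != last:
                if cur in seen or cur not in chosen:
                    return None
                seen.add(cur)
                cur = chosen[cur]
        return chosen

    out = []
    for _ in range(n_shuffles):
        for _attempt in range(10_000):
            chosen = sample_last_edges()
            if chosen is not None:
                break
        else:  # pragma: no cover - only for pathological inputs
            raise RuntimeError("failed to sample a valid Euler-path edge order")
        order: dict[str, list[str]] = {}
        for v in vertices:
            rest = list(edges[v])
            if v in chosen:
                rest.remove(chosen[v])
            rng.shuffle(rest)
            if v in chosen:
                rest.append(chosen[v])
            order[v] = rest
        walk = [first]
        ptr = {v: 0 for v in vertices}
        cur = first
        for _ in range(len(seq) - 1):
            nxt = order[cur][ptr[cur]]
            ptr[cur] += 1
            walk.append(nxt)
            cur = nxt
        out.append("".join(walk))
    return out


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

_PAIR_MATRIX = np.zeros((4, 4))
for (_b1, _b2), _w in PAIR_STACK_WEIGHTS.items():
    _PAIR_MATRIX[NUCLEOTIDES.index(_b1), NUCLEOTIDES.index(_b2)] = _w


def stacking_energy(seq: str) -> float:
    """Energy of the best single helical stem in the window.

    Scans all register offsets (anti-diagonals of the complementarity
    matrix) for the most stable contiguous run of Watson-Crick/GU pairs
    separated by at least :data:`MIN_LOOP` unpaired bases; a stem of one
    pair has no stack and scores 0.  Returns the (negative) stem score,
    or 0.0 when no stem of two or more pairs exists.
    """
    code = np.array([NUCLEOTIDES.index(b) if b in NUCLEOTIDES else -1 for b in seq])
    n = len(code)
    best = 0.0
    for s in range(2 * n - 3):  # anti-diagonal index: i + j == s
        i0 = max(0, s - n + 1)
        i1 = (s - MIN_LOOP - 1) // 2  # innermost pair must enclose >= MIN_LOOP bases
        if i1 < i0:
            continue
        i = np.arange(i0, i1 + 1)
        j = s - i
        ok = (code[i] >= 0) & (code[j] >= 0)
        w = np.where(ok, _PAIR_MATRIX[code[i], code[j]], 0.0)
        # maximal contiguous runs of pairing cells
        run = 0.0
        run_len = 0
        for val in w:
            if val < 0:
                run += val
                run_len += 1
                if run_len >= 2 and run < best:
                    best = run
            else:
                run, run_len = 0.0, 0
    return float(best)


ENERGY_MODELS: dict[str, Callable[[str], float]] = {"stacking": stacking_energy}


# ---------------------------------------------------------------------------
# Z-scores and profiles
# ---------------------------------------------------------------------------


def segment_zscore(
    seq_window: str,
    energy_fn: Callable[[str], float] = stacking_energy,
    n_shuffles: int = 50,
    seed: int | None = None,
) -> float:
    """Z = (E - mu) / sigma against the window's own shuffle distribution.

    Degenerate windows whose shuffles all share one energy (sigma = 0)
    get Z = 0 with a logged flag.
    """
    if not MIN_WINDOW <= len(seq_window) <= MAX_WINDOW:
        raise ValueError(
            f"window length {len(seq_window)} outside [{MIN_WINDOW}, {MAX_WINDOW}]"
        )
    e = energy_fn(seq_window)
    shuf = dinucleotide_shuffle(seq_window, n_shuffles, seed=seed)
    es = np.array([energy_fn(s) for s in shuf])
    sigma = float(es.std())
    if sigma == 0.0:
        logger.debug("segment_zscore: degenerate shuffle distribution, z := 0")
        return 0.0
    return float((e - es.mean()) / sigma)


@dataclass
class StructureProfile:
    """Per-position structural potential of one transcript."""

    transcript_id: str
    z: np.ndarray  # min Z over covering segments where < -2, else NaN
    segments: list[tuple[int, int, float]]  # (start, end, z) with z < -2
    energy_model: str = "stacking"
    n_shuffles: int = 50
    seed: int | None = None

    def z_at(self, pos: int) -> float | None:
        v = self.z[pos]
        return None if np.isnan(v) else float(v)


def annotate_profile(
    transcript: Transcript,
    energy_fn: Callable[[str], float] = stacking_energy,
    stride_start: int = 5,
    stride_len: int = 10,
    min_len: int = MIN_WINDOW,
    max_len: int = MAX_WINDOW,
    n_shuffles: int = 50,
    seed: int | None = None,
    energy_model_id: str = "stacking",
) -> StructureProfile:
    """Slide windows over a transcript; keep segments with Z < -2.

    Window lengths run over [min_len, max_len] at ``stride_len`` and
    starts at ``stride_start`` (exhaustive when both are 1).  Each
    position receives the minimum Z over qualifying segments covering
    it, or null.
    """
    L = len(transcript.cds)
    if L < min_len:
        raise ValueError(f"{transcript.id}: transcript shorter than {min_len} nt")
    z = np.full(L, np.nan)
    segments: list[tuple[int, int, float]] = []
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    widx = 0
    for wlen in range(min_len, min(max_len, L) + 1, stride_len):
        for start in range(0, L - wlen + 1, stride_start):
            widx += 1
            window = transcript.cds[start : start + wlen]
            if any(b not in NUCLEOTIDES for b in window):
                continue
            zval = segment_zscore(
                window, energy_fn, n_shuffles,
                seed=int(ss.generate_state(1)[0] % (2**31)) + widx,
            )
            if zval < Z_THRESHOLD:
                segments.append((start, start + wlen, zval))
                sl = slice(start, start + wlen)
                z[sl] = np.fmin(z[sl], zval)
    return StructureProfile(
        transcript_id=transcript.id, z=z, segments=segments,
        energy_model=energy_model_id, n_shuffles=n_shuffles, seed=seed,
    )


def structure_status_comparison(
    dz: Sequence[float],
    threshold: float = 2.0,
    mode: str = "NCES",
    n_subsample: int = 100,
    compare_to: Sequence[float] | None = None,
    seed: int | None = None,
) -> dict:
    """Tail asymmetry of a ΔZ distribution (edited minus unedited for NCES).

    Counts ΔZ < -threshold vs ΔZ > +threshold and applies a two-sided
    binomial test; a heavier left tail means the edited member of a pair
    sits in stronger structure.  When ``compare_to`` is given, random
    ``n_subsample``-pair samples of the two site classes are additionally
    compared with the Wilcoxon signed-rank test.
    """
    dz = np.asarray(list(dz), dtype=float)
    dz = dz[np.isfinite(dz)]
    if len(dz) < 10:
        logger.warning("structure comparison on only %d pairs", len(dz))
    left = int((dz < -threshold).sum())
    right = int((dz > threshold).sum())
    out = {
        "mode": mode,
        "n_pairs": int(len(dz)),
        "n_left": left,
        "n_right": right,
        "threshold": threshold,
    }
    if left + right == 0:
        out["binomial_p"] = None
        out["skipped"] = True
        return out
    out["binomial_p"] = float(sps.binomtest(left, left + right, 0.5).pvalue)
    out["skipped"] = False
    if compare_to is not None:
        other = np.asarray(list(compare_to), dtype=float)
        other = other[np.isfinite(other)]
        k = min(n_subsample, len(dz), len(other))
        if k >= 10:
            rng = np.random.default_rng(seed)
            a = rng.choice(dz, size=k, replace=False)
            b = rng.choice(other, size=k, replace=False)
            out["wilcoxon_p"] = float(sps.wilcoxon(a, b).pvalue)
    return out


def delta_z(
    profile_pairs: Iterable[tuple[StructureProfile, int, StructureProfile, int]],
) -> np.ndarray:
    """ΔZ (first minus second) per (profile, position) pair; null Z reads 0."""
    out = []
    for p1, pos1, p2, pos2 in profile_pairs:
        z1 = p1.z_at(pos1) or 0.0
        z2 = p2.z_at(pos2) or 0.0
        out.append(z1 - z2)
    return np.array(out)
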