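"""Maximum-parsimony ancestral states and substitution-count matrices.

With only three informative species per comparison, the ancestor of the
focal lineage is inferred by parsimony from the sister species and an
outgroup: the ancestral nucleotide is the one shared by sister and
outgroup, and an ancestral adenine is considered edited only if the
homologous adenines in *both* sister and outgroup are edited.  When the
sister and outgroup nucleotides disagree the column is undetermined.

The resulting matrix tallies #(N_anc -> N_focal) over the alphabet
{A, E, C, G, T}, where the focal state is E iff the focal adenine is
annotated as edited.  Diagonal (no-change) counts are retained: every
rate in the downstream R/Q statistics is per opportunity, and the row
sum is the opportunity count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import (
    A, C, E, G, GAP, N, T,
    MATRIX_ALPHABET,
    AlignedColumn,
    OrthoAlignment,
    SpeciesTriplet,
    Synonymy,
    Transcript,
    position_synonymy_arrays,
)

logger = logging.getLogger(__name__)

UNDETERMINED = "UNDETERMINED"

#: maps internal int state -> index in the 5-letter matrix alphabet
_MATRIX_INDEX = {A: 0, E: 1, C: 2, G: 3, T: 4}
_SYN_CLASSES = (Synonymy.SYN, Synonymy.NONSYN, Synonymy.NONCODING)


@dataclass
class SubstitutionMatrix:
    """MP-inferred substitution counts over {A, E, C, G, T}.

    ``counts[i][j]`` is the number of columns with ancestor
    ``MATRIX_ALPHABET[i]`` and focal state ``MATRIX_ALPHABET[j]``.
    ``by_class`` stratifies the same counts by the synonymy class of an
    A<->G interchange at the focal position (used by the SES/NES splits
    and the editing-aware dN/dS).
    """

    counts: np.ndarray
    focal: str = ""
    sister: str = ""
    outgroup: str = ""
    n_columns: int = 0
    n_skipped: int = 0
    n_undetermined: int = 0
    n_edit_xor: int = 0  # E in exactly one of sister/outgroup -> ancestor A
    el_min: float = 0.0
    by_class: dict[Synonymy, np.ndarray] = field(default_factory=dict)
    n_focal_E: int = 0  # focal E columns among those counted
    n_focal_A: int = 0

    @property
    def alphabet(self) -> tuple[str, ...]:
        return MATRIX_ALPHABET

    def count(self, anc: str, desc: str) -> int:
        return int(self.counts[MATRIX_ALPHABET.index(anc), MATRIX_ALPHABET.index(desc)])

    def row_sum(self, anc: str) -> int:
        return int(self.counts[MATRIX_ALPHABET.index(anc)].sum())

    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=MATRIX_ALPHABET, columns=MATRIX_ALPHABET)


def infer_ancestral_state(
    column: AlignedColumn | dict[str, str], triplet: SpeciesTriplet
) -> str:
    """MP ancestral state of the focal lineage from sister and outgroup.

    Returns one of 'A', 'E', 'C', 'G', 'T' or :data:`UNDETERMINED`.
    E is returned only when both sister and outgroup are edited; if
    exactly one of them is edited the shared nucleotide A is returned
    (editing is not parsimoniously ancestral).  Gap or N in either
    informative species yields UNDETERMINED.
    """
    states = column.states if isinstance(column, AlignedColumn) else column
    s = states[triplet.sister]
    o = states[triplet.outgroup]
    if s in "-N" or o in "-N":
        return UNDETERMINED
    s_nuc = "A" if s == "E" else s
    o_nuc = "A" if o == "E" else o
    if s_nuc != o_nuc:
        return UNDETERMINED
    if s == "E" and o == "E":
        return "E"
    return s_nuc


def _ancestor_codes(
    aln: OrthoAlignment, triplet: SpeciesTriplet
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ancestor per column.

    Returns ``(anc, determinate)`` where ``anc`` holds internal state
    codes (A/E/C/G/T) and ``determinate`` is a boolean mask.
    """
    s = aln.states[triplet.sister]
    o = aln.states[triplet.outgroup]
    s_nuc = np.where(s == E, A, s)
    o_nuc = np.where(o == E, A, o)
    ok = (s != GAP) & (s != N) & (o != GAP) & (o != N) & (s_nuc == o_nuc)
    anc = np.where((s == E) & (o == E), E, s_nuc).astype(np.int8)
    return anc, ok


def build_substitution_matrix(
    alignments: Iterable[OrthoAlignment],
    triplet: SpeciesTriplet,
    transcripts: dict[str, Transcript] | None = None,
    el_min: float = 0.0,
) -> SubstitutionMatrix:
    """Tally #(N_anc -> N_focal) over all columns of all alignments.

    ``transcripts`` (focal species ``{id: Transcript}``) enables the
    per-class stratification needed by the synonymous/nonsynonymous
    splits; without it only the pooled counts are filled.  ``el_min``
    drops focal E columns with editing level below the threshold from
    the tally entirely (they are counted in ``n_skipped``), keeping the
    unedited-A class uncontaminated.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments given")
    counts = np.zeros((5, 5), dtype=np.int64)
    by_class = {cl: np.zeros((5, 5), dtype=np.int64) for cl in _SYN_CLASSES}
    n_cols = n_skip = n_undet = n_xor = 0
    have_classes = transcripts is not None

    for aln in alignments:
        anc, ok = _ancestor_codes(aln, triplet)
        f = aln.states[triplet.focal]
        fe = aln.els[triplet.focal]
        n_cols += aln.n_columns
        n_undet += int((~ok).sum())
        focal_ok = (f != GAP) & (f != N)
        if el_min > 0:
            low = (f == E) & ~(fe >= el_min)
            focal_ok &= ~low
        use = ok & focal_ok
        n_skip += int((ok & ~use).sum())
        s = aln.states[triplet.sister]
        o = aln.states[triplet.outgroup]
        n_xor += int((use & (anc == A) & ((s == E) ^ (o == E))).sum())

        # map internal codes to matrix indices
        remap = np.full(7, -1, dtype=np.int8)
        for st, ix in _MATRIX_INDEX.items():
            remap[st] = ix
        ai = remap[anc[use]]
        fi = remap[f[use]]
        np.add.at(counts, (ai, fi), 1)

        if have_classes:
            tid = aln.transcript_ids.get(triplet.focal)
            tr = transcripts.get(tid) if tid else None
            if tr is None:
                cls = np.full(aln.n_columns, -1, dtype=np.int8)
            else:
                syn, _ = position_synonymy_arrays(tr)
                pos = aln.backmap[triplet.focal]
                cls = np.full(aln.n_columns, -1, dtype=np.int8)
                nongap = pos >= 0
                cls[nongap] = syn[pos[nongap]]
            for cl, val in ((Synonymy.SYN, 1), (Synonymy.NONSYN, 0), (Synonymy.NONCODING, -1)):
                m = use & (cls == val)
                np.add.at(by_class[cl], (remap[anc[m]], remap[f[m]]), 1)

    mat = SubstitutionMatrix(
        counts=counts,
        focal=triplet.focal,
        sister=triplet.sister,
        outgroup=triplet.outgroup,
        n_columns=n_cols,
        n_skipped=n_skip,
        n_undetermined=n_undet,
        n_edit_xor=n_xor,
        el_min=el_min,
        by_class=by_class if have_classes else {},
    )
    mat.n_focal_E = int(counts[:, 1].sum())
    mat.n_focal_A = int(counts[:, 0].sum())
    return mat


def pool_matrices(matrices: Sequence[SubstitutionMatrix]) -> SubstitutionMatrix:
    """Element-wise sum of substitution matrices (the averaged-pair tally)."""
    if not matrices:
        raise ValueError("nothing to pool")
    counts = np.sum([m.counts for m in matrices], axis=0)
    by_class = {}
    if all(m.by_class for m in matrices):
        for cl in _SYN_CLASSES:
            by_class[cl] = np.sum([m.by_class[cl] for m in matrices], axis=0)
    pooled = SubstitutionMatrix(
        counts=counts,
        focal="+".join(m.focal for m in matrices),
        sister="+".join(m.sister for m in matrices),
        outgroup="+".join(m.outgroup for m in matrices),
        n_columns=sum(m.n_columns for m in matrices),
        n_skipped=sum(m.n_skipped for m in matrices),
        n_undetermined=sum(m.n_undetermined for m in matrices),
        n_edit_xor=sum(m.n_edit_xor for m in matrices),
        el_min=matrices[0].el_min,
        by_class=by_class,
    )
    pooled.n_focal_E = sum(m.n_focal_E for m in matrices)
    pooled.n_focal_A = sum(m.n_focal_A for m in matrices)
    return pooled


def write_matrix(mat: SubstitutionMatrix, path) -> None:
    """Write a matrix as TSV with a JSON metadata header block."""
    import json

    meta = {
        "focal": mat.focal,
        "sister": mat.sister,
        "outgroup": mat.outgroup,
        "n_columns": mat.n_columns,
        "n_skipped": mat.n_skipped,
        "n_undetermined": mat.n_undetermined,
        "n_edit_xor": mat.n_edit_xor,
        "el_min": mat.el_min,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("anc\\desc\t" + "\t".join(MATRIX_ALPHABET) + "\n")
        for i, a in enumerate(MATRIX_ALPHABET):
            fh.write(a + "\t" + "\t".join(str(int(x)) for x in mat.counts[i]) + "\n")
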