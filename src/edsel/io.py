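"""Shared data model and readers/writers for the external formats.

Coordinates are 0-based half-open everywhere internally; the editing-site
TSV reader accepts ``one_based=True`` because published supplementary
tables are 1-based.  Editing levels are stored as fractions in [0, 1];
percent-scale inputs (> 1) are converted with a logged warning.
Transcripts are sense-strand mRNA; any non-ACGT base is mapped to N and
excluded from all downstream counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Alphabet encoding.  E denotes an adenine annotated as edited; the
# underlying nucleotide of an E cell is always A.
# ---------------------------------------------------------------------------

A, C, G, T, E, GAP, N = range(7)
STATE_CHARS = "ACGTE-N"
CHAR_TO_STATE = {ch: i for i, ch in enumerate(STATE_CHARS)}
NUCLEOTIDES = "ACGT"
#: substitution-matrix alphabet order used throughout (ancestor x descendant)
MATRIX_ALPHABET = ("A", "E", "C", "G", "T")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

SENSE_CODONS = tuple(sorted(c for c in _CODON_TABLE if _CODON_TABLE[c] != "*"))


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, ``*`` for stop) of a DNA codon."""
    return _CODON_TABLE[codon]


class Synonymy(Enum):
    SYN = "SYN"
    NONSYN = "NONSYN"
    NONCODING = "NONCODING"


@dataclass(frozen=True)
class Transcript:
    """A coding transcript (sense strand, DNA alphabet).

    ``frame_offset`` is the 0-based offset of the first base of codon 1.
    """

    id: str
    species: str
    cds: str
    frame_offset: int = 0

    def __post_init__(self):
        if self.frame_offset < 0:
            raise ValueError(f"{self.id}: negative frame_offset")
        if len(self.cds) < self.frame_offset:
            raise ValueError(f"{self.id}: cds shorter than frame_offset")

    @property
    def n_codons(self) -> int:
        return (len(self.cds) - self.frame_offset) // 3

    def codon_index(self, pos: int) -> tuple[int, int]:
        """(codon number, position-within-codon) for a cds position."""
        off = pos - self.frame_offset
        return off // 3, off % 3

    def codon(self, codon_i: int) -> str:
        s = self.frame_offset + 3 * codon_i
        return self.cds[s : s + 3]


@dataclass(frozen=True)
class EditingSite:
    transcript_id: str
    pos: int
    editing_level: float
    synonymy: Synonymy

    def __post_init__(self):
        if not 0.0 <= self.editing_level <= 1.0:
            raise ValueError(
                f"{self.transcript_id}:{self.pos}: editing level "
                f"{self.editing_level} outside [0, 1]"
            )


@dataclass(frozen=True)
class SpeciesTriplet:
    """Focal species, its closest relative, and an outgroup."""

    focal: str
    sister: str
    outgroup: str

    def __post_init__(self):
        if len({self.focal, self.sister, self.outgroup}) != 3:
            raise ValueError("focal, sister and outgroup must be distinct")


@dataclass
class AlignedColumn:
    """One alignment column: per-species state character and editing level."""

    states: dict[str, str]
    editing_levels: dict[str, float] = field(default_factory=dict)

    def state(self, species: str) -> str:
        return self.states[species]


class OrthoAlignment:
    """A gap-aware orthogroup alignment over the editing-aware alphabet.

    States are stored as int8 arrays (one per species) using the encoding
    in :data:`STATE_CHARS`; ``els`` holds the editing level where the
    state is E (NaN elsewhere).  ``backmap`` maps column index to the
    0-based transcript position (-1 at gaps).
    """

    def __init__(
        self,
        species_order: list[str],
        states: Mapping[str, np.ndarray],
        els: Mapping[str, np.ndarray] | None = None,
        transcript_ids: Mapping[str, str] | None = None,
    ):
        self.species_order = list(species_order)
        lengths = {len(states[s]) for s in self.species_order}
        if len(lengths) != 1:
            raise ValueError("ragged alignment rows")
        (self.n_columns,) = lengths
        self.states = {s: np.asarray(states[s], dtype=np.int8) for s in self.species_order}
        if els is None:
            els = {}
        self.els = {
            s: np.asarray(
                els.get(s, np.full(self.n_columns, np.nan)), dtype=float
            )
            for s in self.species_order
        }
        self.transcript_ids = dict(transcript_ids or {})
        self.backmap = {}
        for s in self.species_order:
            bm = np.full(self.n_columns, -1, dtype=np.int64)
            nongap = self.states[s] != GAP
            bm[nongap] = np.arange(int(nongap.sum()))
            self.backmap[s] = bm

    def __len__(self) -> int:
        return self.n_columns

    def column(self, i: int) -> AlignedColumn:
        return AlignedColumn(
            states={s: STATE_CHARS[self.states[s][i]] for s in self.species_order},
            editing_levels={
                s: float(self.els[s][i])
                for s in self.species_order
                if self.states[s][i] == E
            },
        )

    def columns(self) -> Iterator[AlignedColumn]:
        for i in range(self.n_columns):
            yield self.column(i)

    def column_of_position(self, species: str, pos: int) -> int:
        """Inverse of the back-map for non-gap cells."""
        cols = np.nonzero(self.backmap[species] == pos)[0]
        if len(cols) != 1:
            raise KeyError(f"{species} position {pos} not in alignment")
        return int(cols[0])

    def nucleotide_states(self, species: str) -> np.ndarray:
        """States with the editing layer collapsed (E reported as A)."""
        s = self.states[species].copy()
        s[s == E] = A
        return s


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_IUPAC = set("ACGTUNRYSWKMBDHV")


def _normalize_cds(record_id: str, seq: str) -> str:
    out = []
    for i, ch in enumerate(seq.upper()):
        if ch not in _IUPAC:
            raise ValueError(
                f"record {record_id}: non-IUPAC character {ch!r} at position {i}"
            )
        if ch == "U":
            ch = "T"
        elif ch not in "ACGT":
            ch = "N"  # ambiguity codes excluded from counts downstream
        out.append(ch)
    return "".join(out)


def read_transcripts(
    path: str | Path,
    species: str,
    frame_offsets: Mapping[str, int] | None = None,
) -> dict[str, Transcript]:
    """Read a per-species CDS FASTA into ``{id: Transcript}``.

    Sequences are uppercased, U is mapped to T, other ambiguity codes to N.
    ``frame_offsets`` is an optional sidecar ``{transcript_id: offset}``
    table; the default frame offset is 0.
    """
    frame_offsets = frame_offsets or {}
    out: dict[str, Transcript] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        out[rec.id] = Transcript(
            id=rec.id,
            species=species,
            cds=_normalize_cds(rec.id, str(rec.seq)),
            frame_offset=int(frame_offsets.get(rec.id, 0)),
        )
    return out


def classify_synonymy(transcript: Transcript, pos: int) -> Synonymy:
    """Effect of an A->G change at ``pos``: SYN, NONSYN or NONCODING.

    NONCODING covers positions before the frame offset, beyond the last
    complete codon, and codons containing ambiguous bases.
    """
    if not 0 <= pos < len(transcript.cds):
        raise IndexError(f"{transcript.id}: position {pos} out of range")
    if pos < transcript.frame_offset:
        return Synonymy.NONCODING
    ci, within = transcript.codon_index(pos)
    codon = transcript.codon(ci)
    if len(codon) < 3 or any(b not in NUCLEOTIDES for b in codon):
        return Synonymy.NONCODING
    mutated = codon[:within] + "G" + codon[within + 1 :]
    forced = codon[:within] + "A" + codon[within + 1 :]
    return (
        Synonymy.SYN
        if translate_codon(forced) == translate_codon(mutated)
        else Synonymy.NONSYN
    )


def read_editing_sites(
    path: str | Path,
    transcripts: Mapping[str, Transcript],
    one_based: bool = False,
) -> list[EditingSite]:
    """Read an editing-site TSV (transcript_id, pos, editing_level[, ...]).

    Sites on unknown transcripts or at non-A bases are rejected with a
    logged warning (not fatal).  Editing levels > 1 are interpreted as
    percent and divided by 100 (logged).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "pos", "editing_level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites: list[EditingSite] = []
    for row in df.itertuples(index=False):
        tid = str(row.transcript_id)
        pos = int(row.pos) - (1 if one_based else 0)
        el = float(row.editing_level)
        tr = transcripts.get(tid)
        if tr is None:
            logger.warning("editing site %s:%s: unknown transcript, rejected", tid, pos)
            continue
        if not 0 <= pos < len(tr.cds) or tr.cds[pos] != "A":
            logger.warning(
                "editing site %s:%s: base is %s, not A; rejected",
                tid, pos, tr.cds[pos] if 0 <= pos < len(tr.cds) else "out-of-range",
            )
            continue
        if el > 1.0:
            logger.warning(
                "editing site %s:%s: level %.4g > 1 interpreted as percent", tid, pos, el
            )
            el /= 100.0
        sites.append(
            EditingSite(
                transcript_id=tid,
                pos=pos,
                editing_level=el,
                synonymy=classify_synonymy(tr, pos),
            )
        )
    return sites


def read_alignment(
    path: str | Path,
    species_order: list[str] | None = None,
    editing_sites: Mapping[str, Iterable[EditingSite]] | None = None,
) -> OrthoAlignment:
    """Read an aligned FASTA orthogroup with ``species|transcript_id`` headers.

    Editing annotations are joined per species: an aligned A whose
    transcript position is listed as edited becomes state E and carries
    the editing level.
    """
    rows: dict[str, str] = {}
    tids: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"{path}: header {rec.id!r} lacks 'species|transcript_id'")
        sp, tid = rec.id.split("|", 1)
        if sp in rows:
            raise ValueError(f"{path}: species {sp!r} appears twice")
        rows[sp] = str(rec.seq).upper().replace("U", "T")
        tids[sp] = tid
    if species_order is None:
        species_order = list(rows)
    else:
        missing = set(species_order) - set(rows)
        if missing:
            raise ValueError(f"{path}: species missing from alignment: {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment rows")

    states = {}
    for sp in species_order:
        enc = np.array(
            [CHAR_TO_STATE.get(ch, N) if ch != "-" else GAP for ch in rows[sp]],
            dtype=np.int8,
        )
        states[sp] = enc
    aln = OrthoAlignment(species_order, states, transcript_ids=tids)

    if editing_sites:
        for sp in species_order:
            by_pos = {
                s.pos: s.editing_level
                for s in editing_sites.get(sp, [])
                if s.transcript_id == tids[sp]
            }
            if not by_pos:
                continue
            st, bm, el = aln.states[sp], aln.backmap[sp], aln.els[sp]
            for col in np.nonzero(st == A)[0]:
                lev = by_pos.get(int(bm[col]))
                if lev is not None:
                    st[col] = E
                    el[col] = lev
    return aln


def write_alignment(aln: OrthoAlignment, path: str | Path, width: int = 60) -> None:
    """Write an orthogroup back to aligned FASTA (E written as A)."""
    with open(path, "w") as fh:
        for sp in aln.species_order:
            nuc = aln.nucleotide_states(sp)
            seq = "".join("-" if s == GAP else STATE_CHARS[s] for s in nuc)
            tid = aln.transcript_ids.get(sp, sp)
            fh.write(f">{sp}|{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_editing_sites(sites: Iterable[EditingSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "pos": s.pos,
                "editing_level": s.editing_level,
                "synonymy": s.synonymy.value,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def write_transcripts(transcripts: Mapping[str, Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts.values():
            fh.write(f">{t.id}\n{t.cds}\n")


# ---------------------------------------------------------------------------
# Per-position synonymy tables (vectorized classification support)
# ---------------------------------------------------------------------------

_CODON_IDS = {
    "".join(c): 16 * NUCLEOTIDES.index(c[0])
    + 4 * NUCLEOTIDES.index(c[1])
    + NUCLEOTIDES.index(c[2])
    for c in itertools.product(NUCLEOTIDES, repeat=3)
}

# forced-A synonymy: for codon id c and within-codon position w, the class of
# an A<->G interchange at w in the codon with its base at w replaced by A.
_FORCED_SYN = np.zeros((64, 3), dtype=np.int8)  # 1 = SYN, 0 = NONSYN
_FOURFOLD_THIRD_A = np.zeros(64, dtype=bool)
for _codon, _cid in _CODON_IDS.items():
    for _w in range(3):
        fa = _codon[:_w] + "A" + _codon[_w + 1 :]
        fg = _codon[:_w] + "G" + _codon[_w + 1 :]
        _FORCED_SYN[_cid, _w] = int(translate_codon(fa) == translate_codon(fg))
    fam = _codon[:2]
    aas = {translate_codon(fam + b) for b in NUCLEOTIDES}
    _FOURFOLD_THIRD_A[_cid] = len(aas) == 1


def position_synonymy_arrays(transcript: Transcript) -> tuple[np.ndarray, np.ndarray]:
    """Per-position arrays for a transcript.

    Returns ``(syn, four)`` where ``syn[p]`` is 1 if an A<->G interchange
    at position ``p`` (in the codon with that base forced to A) is
    synonymous, 0 if nonsynonymous, -1 if non-coding/ambiguous; ``four[p]``
    is True at third positions of four-fold degenerate codon families
    (including the four-fold subfamilies of the six-fold families).
    """
    L = len(transcript.cds)
    syn = np.full(L, -1, dtype=np.int8)
    four = np.zeros(L, dtype=bool)
    off = transcript.frame_offset
    ncod = transcript.n_codons
    if ncod == 0:
        return syn, four
    arr = np.frombuffer(
        transcript.cds[off : off + 3 * ncod].encode(), dtype=np.uint8
    )
    code = np.full(arr.shape, -1, dtype=np.int64)
    for i, ch in enumerate(NUCLEOTIDES):
        code[arr == ord(ch)] = i
    codons = code.reshape(ncod, 3)
    valid = (codons >= 0).all(axis=1)
    cids = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
    cids[~valid] = 0
    for w in range(3):
        pos = off + 3 * np.arange(ncod) + w
        vals = _FORCED_SYN[cids, w].astype(np.int8)
        vals[~valid] = -1
        syn[pos] = vals
        if w == 2:
            four[pos] = np.where(valid, _FOURFOLD_THIRD_A[cids], False)
    return syn, four
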