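"""Forward simulation of coding-sequence evolution with A-to-I editing.

The generator emits species-triplet (or quartet) datasets in exactly the
formats the readers consume, together with a ground-truth record that
makes every downstream estimator testable by parameter recovery.

Model
-----
A root CDS is drawn codon-wise uniformly over the 61 sense codons (no
internal stops).  A configurable fraction of root adenines become
editing sites with Beta-distributed editing levels and an ADAR-like
+/-1 context planted by resampling the neighboring bases.  Each species
then descends from the root along its own branch (star topology; branch
lengths in expected substitutions per site) under a K80 process with a
configurable transition/transversion ratio.  At editing-site positions
the rates are scaled multiplicatively: A->G by ``k_EG``, A->C and A->T
by ``k_EY``, and G->A (re-creation of an edited adenine from guanine)
by ``k_GE``.  A descendant site remains edited iff its base is still A;
descendant editing levels are redrawn with correlation ``el_inherit_rho``
to the root level.  Alignments are the true, gapless homology.

All randomness flows from a single seed through spawned per-transcript
streams, so outputs are byte-identical across runs with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from .io import (
    A, C, E, G, T,
    NUCLEOTIDES,
    SENSE_CODONS,
    EditingSite,
    OrthoAlignment,
    SpeciesTriplet,
    Transcript,
    classify_synonymy,
    translate_codon,
    write_editing_sites,
    write_transcripts,
)

logger = logging.getLogger(__name__)

#: ADAR-like default +/-1 preferences: G depleted at -1, G enriched at +1.
DEFAULT_MOTIF = {
    -1: {"A": 0.35, "C": 0.25, "G": 0.05, "T": 0.35},
    +1: {"A": 0.20, "C": 0.10, "G": 0.50, "T": 0.20},
}


@dataclass
class SimConfig:
    """Parameters of the stated synthetic world.

    Branch lengths are expected substitutions/site from the root
    (trifurcating) to each tip.  ``editing_density`` is the fraction of
    root adenines that are editing sites; the field-realistic default is
    0.01 (about 1% of transcriptome adenines are edited in coleoids).
    Editing levels are Beta(el_alpha, el_beta); the default Beta(1, 9)
    gives the low-EL-dominated distribution typical of editing tables.
    """

    n_transcripts: int = 300
    mean_cds_len: int = 900
    tree: dict[str, float] = field(
        default_factory=lambda: {"focal": 0.05, "sister": 0.05, "outgroup": 0.10}
    )
    editing_density: float = 0.01
    el_alpha: float = 1.0
    el_beta: float = 9.0
    k_EG: float = 1.0
    k_EY: float = 1.0
    k_GE: float = 1.0
    ts_tv: float = 2.0
    motif: dict[int, dict[str, float]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIF.items()}
    )
    hairpin_prob: float = 0.0
    hairpin_stem: int = 12
    el_inherit_rho: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1 or self.mean_cds_len < 30:
            raise ValueError("need >= 1 transcript of >= 30 nt")
        if not 0 <= self.editing_density <= 1:
            raise ValueError("editing_density must be a fraction of adenines")
        for k in ("k_EG", "k_EY", "k_GE", "ts_tv"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        if any(t <= 0 for t in self.tree.values()):
            raise ValueError("branch lengths must be > 0")
        if not 0 <= self.el_inherit_rho <= 1:
            raise ValueError("el_inherit_rho must be in [0, 1]")


@dataclass
class TranscriptTruth:
    """Realized history for one transcript (star tree: root -> each tip).

    ``site_pos`` holds every editable position: root-edited adenines plus
    latent editable non-A positions (where a substitution to A yields an
    edited adenine — the ancestral-G/C/T case of editing-site birth).
    """

    root: np.ndarray  # int codes over ACGT
    site_pos: np.ndarray  # editable positions (ascending)
    root_edited: np.ndarray  # bool over site_pos (False = latent G site)
    root_el: np.ndarray  # editing level per site_pos (NaN at latent sites)
    tip_states: dict[str, np.ndarray]
    tip_els: dict[str, np.ndarray]  # per site_pos; NaN when not edited at tip
    hairpins: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def edit_pos(self) -> np.ndarray:
        """Root-edited site positions."""
        return self.site_pos[self.root_edited]


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, internally recountable."""

    config: SimConfig
    transcripts: dict[str, TranscriptTruth]
    coupling_window: int | None = None

    def species(self) -> list[str]:
        return list(self.config.tree)

    def tip_edited_mask(self, tt: TranscriptTruth, sp: str) -> np.ndarray:
        """Boolean mask over site_pos: edited at this tip (base is A)."""
        return tt.tip_states[sp][tt.site_pos] == A

    def recount_matrix(
        self, triplet: SpeciesTriplet, use_true_ancestor: bool = False,
        el_min: float = 0.0,
    ) -> np.ndarray:
        """5x5 recount of #(anc -> focal) from the realized history.

        With ``use_true_ancestor=False`` the ancestor is re-derived by
        the MP rule from the sister and outgroup tip states (the set of
        columns a downstream matrix build uses); with True, the actual
        root state (with root editing status) is used on the same
        determinate-column set.
        """
        remap = np.zeros(7, dtype=np.int8)
        for st, ix in ((A, 0), (E, 1), (C, 2), (G, 3), (T, 4)):
            remap[st] = ix
        out = np.zeros((5, 5), dtype=np.int64)
        for tt in self.transcripts.values():
            L = len(tt.root)
            is_site = np.zeros(L, dtype=bool)
            is_site[tt.site_pos] = True

            s = tt.tip_states[triplet.sister]
            o = tt.tip_states[triplet.outgroup]
            det = s == o  # MP-determinate nucleotide layer (E reads as A)
            s_ed = is_site & (s == A)
            o_ed = is_site & (o == A)
            anc = np.where(s_ed & o_ed, E, s).astype(np.int8)
            if use_true_ancestor:
                root_e = np.zeros(L, dtype=bool)
                root_e[tt.site_pos[tt.root_edited]] = True
                anc = np.where(root_e, E, tt.root).astype(np.int8)

            f = tt.tip_states[triplet.focal]
            f_ed = is_site & (f == A)
            keep = np.ones(L, dtype=bool)
            if el_min > 0:
                els = np.full(L, np.nan)
                els[tt.site_pos] = tt.tip_els[triplet.focal]
                keep = ~f_ed | (els >= el_min)
            fx = np.where(f_ed, E, f).astype(np.int8)

            m = det & keep
            np.add.at(out, (remap[anc[m]], remap[fx[m]]), 1)
        return out


@dataclass
class SimDataset:
    transcripts: dict[str, dict[str, Transcript]]
    sites: dict[str, list[EditingSite]]
    alignments: list[OrthoAlignment]
    truth: SimTruth


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------


def _k80_q(ts_tv: float) -> np.ndarray:
    """K80 generator normalized to one expected substitution per unit time."""
    kappa = ts_tv
    beta = 1.0 / (kappa + 2.0)
    q = np.full((4, 4), beta)
    transitions = [(A, G), (G, A), (C, T), (T, C)]
    for i, j in transitions:
        q[i, j] = kappa * beta
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _transition_matrices(cfg: SimConfig, t: float) -> np.ndarray:
    """P(t) for the two site categories: [normal, editing-site]."""
    q0 = _k80_q(cfg.ts_tv)
    q1 = q0.copy()
    q1[A, G] *= cfg.k_EG
    q1[A, C] *= cfg.k_EY
    q1[A, T] *= cfg.k_EY
    q1[G, A] *= cfg.k_GE
    np.fill_diagonal(q1, 0.0)
    np.fill_diagonal(q1, -q1.sum(axis=1))
    return np.stack([expm(q0 * t), expm(q1 * t)])


def _sample_children(
    parent: np.ndarray, cat: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    probs = p[cat, parent, :]
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(parent))
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# Root construction
# ---------------------------------------------------------------------------

_CODON_INTS = np.array(
    [[NUCLEOTIDES.index(b) for b in codon] for codon in SENSE_CODONS], dtype=np.int8
)


def _draw_root(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return _CODON_INTS[idx].reshape(-1)


def _codon_has_stop(seq: np.ndarray, pos: int) -> bool:
    ci = pos // 3
    codon = "".join(NUCLEOTIDES[b] for b in seq[3 * ci : 3 * ci + 3])
    return translate_codon(codon) == "*"


def _plant_motif(
    seq: np.ndarray,
    edit_pos: np.ndarray,
    motif: dict[int, dict[str, float]],
    rng: np.random.Generator,
) -> None:
    """Resample the -1/+1 neighbors of edited sites per the motif weights.

    Skips neighbors that are themselves editing sites and redraws (up to
    10 times) if a change would create an internal stop codon.
    """
    site_set = set(int(p) for p in edit_pos)
    for pos in edit_pos:
        for offset, weights in motif.items():
            npos = int(pos) + offset
            if not 0 <= npos < len(seq) or npos in site_set:
                continue
            bases = list(weights)
            p = np.array([weights[b] for b in bases], dtype=float)
            p /= p.sum()
            old = seq[npos]
            for _ in range(10):
                seq[npos] = NUCLEOTIDES.index(bases[rng.choice(len(bases), p=p)])
                if not _codon_has_stop(seq, npos):
                    break
                seq[npos] = old


_COMPLEMENT = np.array([T, G, C, A], dtype=np.int8)  # A<->T, C<->G


def _plant_hairpins(
    seq: np.ndarray,
    edit_pos: np.ndarray,
    prob: float,
    stem: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Embed a perfect stem around a fraction of edited sites.

    The downstream arm [pos+3, pos+3+stem) is overwritten with the
    reverse complement of the upstream arm [pos-3-stem, pos-3), forming
    a hairpin with the edited adenine in the loop.  Sites too close to
    transcript ends or to other editing sites are skipped.
    """
    planted = []
    planted_spans: list[tuple[int, int]] = []
    site_set = set(int(p) for p in edit_pos)
    for pos in edit_pos:
        if rng.random() >= prob:
            continue
        up0, up1 = int(pos) - 3 - stem, int(pos) - 3
        dn0, dn1 = int(pos) + 3, int(pos) + 3 + stem
        if up0 < 0 or dn1 > len(seq):
            continue
        if any(q in site_set for q in range(dn0, dn1)):
            continue
        # keep planted hairpins disjoint so no arm is overwritten later
        if any(up0 < e and s < dn1 for s, e in planted_spans):
            continue
        seq[dn0:dn1] = _COMPLEMENT[seq[up0:up1][::-1]]
        planted_spans.append((up0, dn1))
        planted.append((up0, dn1, stem))
    return planted


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate a species-triplet/quartet dataset with known ground truth."""
    config.validate()
    species = list(config.tree)
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(config.n_transcripts)]
    pmats = {sp: _transition_matrices(config, t) for sp, t in config.tree.items()}

    truths: dict[str, TranscriptTruth] = {}
    transcripts = {sp: {} for sp in species}
    sites = {sp: [] for sp in species}
    alignments: list[OrthoAlignment] = []

    mean_codons = max(10, config.mean_cds_len // 3)
    for ti in range(config.n_transcripts):
        rng = streams[ti]
        tid = f"t{ti:05d}"
        n_codons = max(10, int(rng.poisson(mean_codons)))
        root = _draw_root(n_codons, rng)
        L = len(root)

        a_pos = np.nonzero(root == A)[0]
        n_edit = rng.binomial(len(a_pos), config.editing_density)
        edit_pos = np.sort(rng.choice(a_pos, size=n_edit, replace=False))
        # latent editable positions: a non-A base here that mutates to A
        # yields an edited adenine (editing-site birth from an ancestral
        # G, C or T); same density among non-A bases as edited sites
        # among adenines.  Only the G->A channel carries k_GE.
        non_a = np.nonzero(root != A)[0]
        n_lat = rng.binomial(len(non_a), config.editing_density)
        lat_pos = np.sort(rng.choice(non_a, size=n_lat, replace=False))
        site_pos = np.sort(np.concatenate([edit_pos, lat_pos]))
        root_edited = np.isin(site_pos, edit_pos)
        root_el = np.full(len(site_pos), np.nan)
        root_el[root_edited] = rng.beta(
            config.el_alpha, config.el_beta, size=int(root_edited.sum())
        )

        if config.motif and n_edit:
            _plant_motif(root, edit_pos, config.motif, rng)
        hairpins = []
        if config.hairpin_prob > 0 and n_edit:
            hairpins = _plant_hairpins(
                root, edit_pos, config.hairpin_prob, config.hairpin_stem, rng
            )

        cat = np.zeros(L, dtype=np.int8)
        cat[site_pos] = 1

        tip_states, tip_els = {}, {}
        for sp in species:
            child = _sample_children(root, cat, pmats[sp], rng)
            els = np.full(len(site_pos), np.nan)
            still_a = child[site_pos] == A
            fresh = rng.beta(config.el_alpha, config.el_beta, size=len(site_pos))
            rho = config.el_inherit_rho
            inherit = still_a & root_edited
            born = still_a & ~root_edited
            els[inherit] = np.clip(
                rho * root_el[inherit] + (1 - rho) * fresh[inherit], 0.0, 1.0
            )
            els[born] = fresh[born]
            tip_states[sp] = child
            tip_els[sp] = els

        tt = TranscriptTruth(
            root=root, site_pos=site_pos, root_edited=root_edited, root_el=root_el,
            tip_states=tip_states, tip_els=tip_els, hairpins=hairpins,
        )
        truths[tid] = tt

        # emit per-species transcripts, site tables and the true alignment
        states, els_cols, tids = {}, {}, {}
        for sp in species:
            seq = "".join(NUCLEOTIDES[b] for b in tt.tip_states[sp])
            tr = Transcript(id=tid, species=sp, cds=seq)
            transcripts[sp][tid] = tr
            col = tt.tip_states[sp].astype(np.int8).copy()
            el_col = np.full(L, np.nan)
            mask = tt.tip_states[sp][site_pos] == A
            for p, lev in zip(site_pos[mask], tt.tip_els[sp][mask]):
                col[p] = E
                el_col[p] = lev
                sites[sp].append(
                    EditingSite(
                        transcript_id=tid,
                        pos=int(p),
                        editing_level=float(lev),
                        synonymy=classify_synonymy(tr, int(p)),
                    )
                )
            states[sp] = col
            els_cols[sp] = el_col
            tids[sp] = tid
        alignments.append(
            OrthoAlignment(species, states, els_cols, transcript_ids=tids)
        )

    return SimDataset(
        transcripts=transcripts,
        sites=sites,
        alignments=alignments,
        truth=SimTruth(config=config, transcripts=truths),
    )


def plant_el_context_coupling(
    config: SimConfig,
    window: int = 100,
    base_delta: float = 0.30,
    slope: float = 0.12,
    noise_sd: float = 0.075,
    pair: tuple[str, str] = ("focal", "sister"),
) -> SimDataset:
    """Simulate, then couple |ΔEL| at conserved sites to local divergence.

    For every conserved editing site of the chosen species pair the
    absolute editing-level difference is overwritten with a monotone
    function of the number of nucleotide mismatches within the
    ``window``-nt window centered on the site (plus Gaussian noise), so
    the planted window span can be recovered as the argmax of the
    window-size/|ΔEL| correlation curve.  ``slope=0`` plants zero
    coupling.  The planted window is recorded in the truth record.
    """
    if window > config.mean_cds_len:
        raise ValueError("coupling window exceeds mean transcript length")
    ds = simulate_dataset(config)
    sp1, sp2 = pair
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 987654321)))
    half = window // 2

    # first pass: mismatch counts for all conserved sites
    records = []  # (tid, pos, mismatches)
    for tid, tt in ds.truth.transcripts.items():
        s1, s2 = tt.tip_states[sp1], tt.tip_states[sp2]
        mism = (s1 != s2).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(mism)])
        for k, p in enumerate(tt.site_pos):
            if s1[p] == A and s2[p] == A:
                lo, hi = max(0, p - half), min(len(mism), p + half + 1)
                m = int(cs[hi] - cs[lo] - mism[p])
                records.append((tid, int(p), k, m))
    if not records:
        return ds
    mvals = np.array([r[3] for r in records], dtype=float)
    sd = mvals.std()
    x = (mvals - mvals.mean()) / sd if sd > 0 else np.zeros_like(mvals)

    deltas = np.clip(
        base_delta + slope * x + rng.normal(0.0, noise_sd, size=len(x)), 0.02, 0.9
    )
    signs = rng.choice([-1.0, 1.0], size=len(x))
    new_els = {}
    for (tid, pos, k, _m), d, sgn in zip(records, deltas, signs):
        el_hi, el_lo = 0.5 + d / 2, 0.5 - d / 2
        e1, e2 = (el_hi, el_lo) if sgn > 0 else (el_lo, el_hi)
        tt = ds.truth.transcripts[tid]
        tt.tip_els[sp1][k] = e1
        tt.tip_els[sp2][k] = e2
        new_els[(sp1, tid, pos)] = e1
        new_els[(sp2, tid, pos)] = e2

    # propagate into site tables and alignments
    for sp in (sp1, sp2):
        sites = []
        for s in ds.sites[sp]:
            lev = new_els.get((sp, s.transcript_id, s.pos))
            sites.append(
                dataclasses.replace(s, editing_level=lev) if lev is not None else s
            )
        ds.sites[sp] = sites
    for aln in ds.alignments:
        for sp in (sp1, sp2):
            tid = aln.transcript_ids[sp]
            for col in np.nonzero(aln.states[sp] == E)[0]:
                lev = new_els.get((sp, tid, int(col)))
                if lev is not None:
                    aln.els[sp][col] = lev
    ds.truth.coupling_window = window if slope != 0 else None
    return ds


# ---------------------------------------------------------------------------
# Emission to disk (exactly the formats the readers consume)
# ---------------------------------------------------------------------------


def write_dataset(ds: SimDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    for sp in ds.transcripts:
        write_transcripts(ds.transcripts[sp], outdir / f"{sp}.cds.fasta")
        write_editing_sites(ds.sites[sp], outdir / f"{sp}.sites.tsv")
    for aln in ds.alignments:
        tid = next(iter(aln.transcript_ids.values()))
        path = outdir / "alignments" / f"{tid}.aln.fasta"
        with open(path, "w") as fh:
            for sp in aln.species_order:
                seq = "".join(
                    "-" if s == 5 else "ACGTE-N"[s] for s in aln.nucleotide_states(sp)
                )
                fh.write(f">{sp}|{aln.transcript_ids[sp]}\n{seq}\n")
    truth = {
        "config": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(ds.truth.config).items()
        },
        "coupling_window": ds.truth.coupling_window,
        "transcripts": {
            tid: {
                "root": "".join(NUCLEOTIDES[b] for b in tt.root),
                "site_pos": tt.site_pos.tolist(),
                "root_edited": tt.root_edited.tolist(),
                "root_el": np.round(tt.root_el, 6).tolist(),
                "tips": {
                    sp: "".join(NUCLEOTIDES[b] for b in tt.tip_states[sp])
                    for sp in tt.tip_states
                },
                "hairpins": tt.hairpins,
            }
            for tid, tt in ds.truth.transcripts.items()
        },
    }
    with open(outdir / "sim_truth.json", "w") as fh:
        json.dump(truth, fh)
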