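"""End-to-end orchestration: read/simulate -> ancestry -> statistics ->
context -> (optional) structure -> popgen, with a reproducibility manifest.

Every tunable that affects numbers is carried in :class:`RunConfig` and
written to ``manifest.json``; all randomness flows from the single seed.
Stage failures abort with a stage-named error; files of the failing
stage keep a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import SpeciesTriplet, build_substitution_matrix, pool_matrices, write_matrix
from .context import context_counts, context_mismatch_R, motif_bitscore, window_el_correlation
from .io import (
    OrthoAlignment,
    Synonymy,
    read_alignment,
    read_editing_sites,
    read_transcripts,
)
from .popgen import FixationParams, first_fixation_probability, race_monte_carlo
from .simulate import SimConfig, simulate_dataset, write_dataset
from .stats import (
    codon_weights,
    directed_R_from,
    directed_R_to,
    dnds_edited_vs_unedited,
    dnds_positive_selection,
    el_bins,
    estimates_to_frame,
    mismatch_R,
    pair_table,
    q_backward,
    q_forward,
    r_syn_nonsyn_split,
)
from .structure import annotate_profile

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


@dataclass
class RunConfig:
    """Run settings (all tunables that affect numbers)."""

    focal: str = "focal"
    sister: str = "sister"
    outgroup: str = "outgroup"
    data_dir: str | None = None  # read an existing dataset from here
    out_dir: str = "edsel_out"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    el_bin_width: float = 0.10
    el_min: float = 0.0
    el_strong: float = 0.8  # "strongly edited" default threshold
    dnds_thresholds: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    seed: int = 0
    reps: int = 100_000
    one_based_sites: bool = False
    run_structure: bool = False
    structure_stride_start: int = 5
    structure_stride_len: int = 10
    structure_shuffles: int = 50
    pseudocount: float = 0.0  # exploratory only; 0 = no pseudocounts (default behavior)
    motif_k: int = 5
    window_sizes: tuple[int, ...] = tuple(range(20, 201, 10))

    def species(self) -> list[str]:
        return [self.focal, self.sister, self.outgroup]

    def triplet(self, focal: str | None = None) -> SpeciesTriplet:
        roles = self.species()
        if focal is None or focal == self.focal:
            return SpeciesTriplet(self.focal, self.sister, self.outgroup)
        if focal == self.sister:
            return SpeciesTriplet(self.sister, self.focal, self.outgroup)
        raise ValueError(f"unknown focal species {focal!r}; roles are {roles}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.pop("sim", {}))
    cfg = RunConfig(sim=sim, **{k: v for k, v in raw.items()})
    if abs(round(1 / cfg.el_bin_width) * cfg.el_bin_width - 1.0) > 1e-9:
        raise ValueError("el_bin_width must divide 1 evenly")
    return cfg


def load_dataset(data_dir: str | Path, species: list[str], one_based: bool = False):
    """Read {sp}.cds.fasta, {sp}.sites.tsv and alignments/*.fasta."""
    data_dir = Path(data_dir)
    transcripts, sites = {}, {}
    for sp in species:
        fa = data_dir / f"{sp}.cds.fasta"
        if not fa.exists():
            raise FileNotFoundError(f"missing transcript FASTA {fa}")
        transcripts[sp] = read_transcripts(fa, sp)
        tsv = data_dir / f"{sp}.sites.tsv"
        if not tsv.exists():
            raise FileNotFoundError(f"missing editing-site table {tsv}")
        sites[sp] = read_editing_sites(tsv, transcripts[sp], one_based=one_based)
    alignments = [
        read_alignment(p, species_order=species, editing_sites=sites)
        for p in sorted((data_dir / "alignments").glob("*.fasta"))
    ]
    if not alignments:
        raise FileNotFoundError(f"no alignments under {data_dir / 'alignments'}")
    return transcripts, sites, alignments


def _finalize(paths: list[Path]) -> None:
    for p in paths:
        p.rename(p.with_name(p.name.removesuffix(".partial")))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "settings": _settings_dict(config),
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)

        return deco

    state: dict = {}

    @stage("input")
    def _input():
        if config.simulate:
            ds = simulate_dataset(config.sim)
            write_dataset(ds, out / "dataset")
            state.update(
                transcripts=ds.transcripts, sites=ds.sites, alignments=ds.alignments
            )
        else:
            if not config.data_dir:
                raise ValueError("data_dir required when simulate is false")
            tr, si, al = load_dataset(
                config.data_dir, config.species(), config.one_based_sites
            )
            state.update(transcripts=tr, sites=si, alignments=al)

    @stage("ancestry")
    def _ancestry():
        mats = []
        for focal in (config.focal, config.sister):
            trip = config.triplet(focal)
            m = build_substitution_matrix(
                state["alignments"], trip,
                transcripts=state["transcripts"][focal], el_min=config.el_min,
            )
            mats.append(m)
            p = out / f"subst_matrix.{focal}.tsv.partial"
            write_matrix(m, p)
            _finalize([p])
        pooled = pool_matrices(mats)
        p = out / "subst_matrix.pooled.tsv.partial"
        write_matrix(pooled, p)
        _finalize([p])
        state["matrices"] = mats
        state["pooled"] = pooled

    @stage("selection_stats")
    def _stats():
        pooled = state["pooled"]
        reps, seed = config.reps, config.seed
        ests = [
            directed_R_to(pooled, "G", reps=reps, seed=seed),
            directed_R_to(pooled, "Y", reps=reps, seed=seed + 1),
            directed_R_from(pooled, "G", reps=reps, seed=seed + 2),
            directed_R_from(pooled, "Y", reps=reps, seed=seed + 3),
            q_forward(pooled, reps=reps, seed=seed + 4),
            q_backward(pooled, reps=reps, seed=seed + 5),
        ]
        for cl, est in r_syn_nonsyn_split(pooled, "to", "G", reps=reps, seed=seed + 6).items():
            ests.append(est)
        pairs = pair_table(
            state["alignments"], config.focal, config.sister, state["transcripts"]
        )
        state["pairs"] = pairs
        for bin_ in el_bins(config.el_bin_width):
            est = mismatch_R(pairs, "G", el_range=bin_, reps=reps, seed=seed + 7)
            ests.append(est)
        binned, r, p_f = dnds_edited_vs_unedited(
            pairs, "G", bin_width=config.el_bin_width, reps=reps, seed=seed + 8
        )
        ests.extend(binned)
        weights = codon_weights(state["transcripts"][config.focal])
        sweep = dnds_positive_selection(
            state["alignments"], config.triplet(), state["transcripts"][config.focal],
            weights, config.dnds_thresholds, reps=reps, seed=seed + 9,
        )
        ests.extend(sweep)
        p = out / "selection_stats.tsv.partial"
        estimates_to_frame(ests).to_csv(p, sep="\t", index=False)
        _finalize([p])
        manifest["dnds_el_trend"] = {"pearson_r": r, "f_test_p": p_f}

    @stage("context")
    def _context():
        focal_tr = state["transcripts"][config.focal]
        lo = motif_bitscore(
            state["sites"][config.focal], focal_tr,
            el_range=(0.0, config.el_strong), k=config.motif_k,
        )
        hi_sites = [
            s for s in state["sites"][config.focal]
            if s.editing_level >= config.el_strong
        ]
        rows = [
            {"stratum": "weak", "offset": o, "bits": lo.bits[o],
             **{b: lo.frequencies.loc[o, b] for b in "ACGT"}}
            for o in lo.offsets
        ]
        if len(hi_sites) >= 5:
            hi = motif_bitscore(hi_sites, focal_tr, k=config.motif_k)
            rows += [
                {"stratum": "strong", "offset": o, "bits": hi.bits[o],
                 **{b: hi.frequencies.loc[o, b] for b in "ACGT"}}
                for o in hi.offsets
            ]
        p = out / "motif.tsv.partial"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        cc = context_counts(
            state["alignments"], config.focal, config.sister, state["transcripts"]
        )
        ctx_rows = []
        for side in (+1, -1):
            for n1 in "ACGT":
                for n2 in "ACGT":
                    if n1 == n2:
                        continue
                    est = context_mismatch_R(cc, n1, n2, side=side)
                    row = est.as_row()
                    row["side"] = side
                    ctx_rows.append(row)
        p2 = out / "context_R.tsv.partial"
        pd.DataFrame(ctx_rows).to_csv(p2, sep="\t", index=False)
        curve, argmax = window_el_correlation(
            state["alignments"], config.focal, config.sister,
            window_sizes=config.window_sizes,
        )
        p3 = out / "window_correlation.tsv.partial"
        curve.to_csv(p3, sep="\t", index=False)
        manifest["window_argmax"] = argmax
        _finalize([p, p2, p3])

    if config.run_structure:

        @stage("structure")
        def _structure():
            rows = []
            for tid, tr in list(state["transcripts"][config.focal].items())[:20]:
                prof = annotate_profile(
                    tr,
                    stride_start=config.structure_stride_start,
                    stride_len=config.structure_stride_len,
                    n_shuffles=config.structure_shuffles,
                    seed=config.seed,
                )
                for s0, s1, zv in prof.segments:
                    rows.append(
                        {"transcript": tid, "start": s0, "end": s1, "z": zv,
                         "energy_model": prof.energy_model}
                    )
            p = out / "structured_segments.tsv.partial"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            _finalize([p])

    @stage("manifest")
    def _manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return manifest


def _settings_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"] = dataclasses.asdict(config.sim)
    return d


def race_report(params: FixationParams, n_reps: int, seed: int | None) -> dict:
    closed = first_fixation_probability(params)
    mc = race_monte_carlo(params, n_reps=n_reps, seed=seed)
    return {
        "params": dataclasses.asdict(params),
        "first_fixation_probability": closed,
        "monte_carlo": mc,
        "n_reps": n_reps,
    }
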