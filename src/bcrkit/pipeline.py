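"""End-to-end pipeline: simulate -> annotate -> stats -> clonal -> diverge.

A :class:`PipelineConfig` (buildable from YAML) drives the stages; every
stochastic stage consumes a named sub-seed spawned from the global seed,
so a rerun with the same config produces byte-identical TSV outputs.  A
JSON manifest records the package version, seed, a hash of the
configuration and per-stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationParams, annotate_reads
from .clonal import (
    group_clonotypes,
    group_lineages,
    lineage_dendrogram,
    lineage_members,
    lineage_profile,
    top_lineages,
)
from .divergence import divergence_analysis
from .germline import GermlineDatabase, load_germline, write_germline
from .io import write_fasta, write_rearrangement_tsv
from .simulate import SimulationConfig, simulate_repertoire
from .stats import (
    cdr3_length_distribution,
    circos_export,
    np_addition_distribution,
    productive_fraction,
    sample_diversity,
    usage_frequencies,
    vdj_links,
)
from .toydata import toy_germline

_STAGES = ("simulate", "annotate", "stats", "clonal", "diverge")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``simulation`` holds :class:`SimulationConfig` fields (seed excluded —
    sub-seeds are derived from the global seed); ``second_sample``
    overrides for the comparison sample simulated when the ``diverge``
    stage is enabled (by default a higher SHM rate, emulating an
    immunized sample as sample 1).
    """

    out_dir: str = "bcrkit_run"
    seed: int = 0
    locus: str = "IGH"
    germline_fasta: str | None = None
    germline_meta: str | None = None
    stages: list[str] = field(default_factory=lambda: ["simulate", "annotate", "stats", "clonal"])
    collapse_duplicates: bool = False
    simulation: dict = field(default_factory=dict)
    second_sample: dict = field(default_factory=lambda: {"shm_rate": 0.005})
    annotation: dict = field(default_factory=dict)
    stats: dict = field(default_factory=lambda: {"level": "subfamily"})
    clonal: dict = field(default_factory=lambda: {"top_n": 10, "dendrogram_top": 3})
    divergence: dict = field(default_factory=lambda: {"min_copies": 100, "p_cutoff": 0.01})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in _STAGES:
                raise ConfigError(f"unknown stage {stage!r}; known: {_STAGES}")
        if (self.germline_fasta is None) != (self.germline_meta is None):
            raise ConfigError("germline_fasta and germline_meta must be given together")
        for path in (self.germline_fasta, self.germline_meta):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"germline path does not exist: {path}")
        # fail on unknown simulation keys before any compute
        SimulationConfig.from_dict({**self.simulation, "locus": self.locus})

    def config_hash(self) -> str:
        # hash the scientific parameters, not the output location
        data = asdict(self)
        data.pop("out_dir", None)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(out_dir: str | Path, seed: int = 1, n_reads: int = 2000) -> PipelineConfig:
    """The bundled end-to-end demo: toy germline, clonally expanded IGH
    sample, full stats/clonal stages."""
    return PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        simulation={
            "n_reads": n_reads,
            "n_lineages": max(20, n_reads // 10),
            "shm_rate": 0.01,
        },
    )


def _sub_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, db: GermlineDatabase | None = None) -> dict:
    """Execute the configured stages; returns the manifest (also written
    to ``out_dir/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    manifest: dict = {
        "package": "bcrkit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if db is None:
        if config.germline_fasta:
            db = load_germline(config.germline_fasta, config.germline_meta)
        else:
            db = toy_germline()
            gdir = out / "germline"
            gdir.mkdir(exist_ok=True)
            write_germline(db, gdir / "germline.fasta", gdir / "germline.tsv")

    ann_params = AnnotationParams(**config.annotation)
    tables = {}

    samples = [("s1", config.simulation)]
    if "diverge" in config.stages:
        samples.append(("s2", {**config.simulation, **config.second_sample}))

    # both samples share one sub-seed: with the diverge stage enabled the
    # comparison sample is built from the same founder rearrangements
    # (paired design, e.g. immunized vs unimmunized of one repertoire)
    # and differs only through its SHM parameters
    sim_seed = _sub_seed(root, 0)
    for label, sim_overrides in samples:
        if "simulate" not in config.stages:
            break
        sim_cfg = SimulationConfig.from_dict(
            {**sim_overrides, "locus": config.locus, "seed": sim_seed}
        )
        rep = simulate_repertoire(db, sim_cfg)
        write_fasta(rep.reads, out / f"reads_{label}.fasta")
        rep.truth.to_csv(out / f"truth_{label}.tsv", sep="\t", index=False)
        manifest["stages"].setdefault("simulate", {})[label] = {
            "n_reads": len(rep.reads),
            "reads": f"reads_{label}.fasta",
            "truth": f"truth_{label}.tsv",
        }
        if "annotate" in config.stages:
            res = annotate_reads(
                rep.reads, db, config.locus, ann_params,
                collapse_duplicates=config.collapse_duplicates,
            )
            write_rearrangement_tsv(res.table, out / f"rearrangements_{label}.tsv")
            tables[label] = res.table
            manifest["stages"].setdefault("annotate", {})[label] = {
                "n_input": res.n_input,
                "n_annotated": res.n_annotated,
                "n_unannotatable": res.n_unannotatable,
                "table": f"rearrangements_{label}.tsv",
            }

    if "stats" in config.stages and "s1" in tables:
        table = tables["s1"]
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        level = config.stats.get("level", "subfamily")
        for seg_type in ("V", "D", "J") if config.locus == "IGH" else ("V", "J"):
            usage = usage_frequencies(table, seg_type)
            usage.to_csv(sdir / f"usage_{seg_type}.tsv", sep="\t", index=False)
        links = vdj_links(table, level=level)
        links.to_csv(sdir / "vdj_links.tsv", sep="\t", index=False)
        circos_export(links, sdir / "circos_karyotype.txt", sdir / "circos_links.txt")
        cdr3 = cdr3_length_distribution(table)
        cdr3.to_csv(sdir / "cdr3_lengths.tsv", sep="\t", index=False)
        np_hists = np_addition_distribution(table)
        np_frame = pd.concat(
            [h.rename_axis("length").reset_index(name="count").assign(region=name)
             for name, h in np_hists.items()],
            ignore_index=True,
        )
        np_frame.to_csv(sdir / "np_lengths.tsv", sep="\t", index=False)
        summary = {
            "productive_fraction_percent": productive_fraction(table),
            "mean_cdr3_length_aa": cdr3.attrs["mean_length"],
            "shannon_h_prime": sample_diversity(table).h_prime,
            "n_species": sample_diversity(table).n_species,
            "mean_n1_length": np_hists["n1"].attrs["mean"],
        }
        with open(sdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest["stages"]["stats"] = {"dir": "stats", **summary}

    if "clonal" in config.stages and "s1" in tables:
        table = tables["s1"]
        cdir = out / "clonal"
        cdir.mkdir(exist_ok=True)
        clonotypes = group_clonotypes(table)
        clonotypes.to_csv(cdir / "clonotypes.tsv", sep="\t", index=False)
        lineages = group_lineages(table, level=config.clonal.get("level", "gene"))
        lineages.to_csv(cdir / "lineages.tsv", sep="\t", index=False)
        top = top_lineages(lineages, config.clonal.get("top_n", 10))
        for _, row in top.head(config.clonal.get("dendrogram_top", 3)).iterrows():
            members = lineage_members(table, row)
            profile = lineage_profile(members, db)
            profile.as_frame().to_csv(cdir / f"profile_{row['name']}.tsv", sep="\t", index=False)
            if members["cdr3_aa"].fillna("").ne("").sum() >= 1:
                tree = lineage_dendrogram(members)
                (cdir / f"tree_{row['name']}.nwk").write_text(tree.newick + "\n")
                tree.overlay.to_csv(cdir / f"overlay_{row['name']}.tsv", sep="\t", index=False)
        manifest["stages"]["clonal"] = {
            "n_clonotypes": int(len(clonotypes)),
            "n_lineages": int(len(lineages)),
            "dir": "clonal",
        }

    if "diverge" in config.stages and "s1" in tables and "s2" in tables:
        result = divergence_analysis(
            tables["s1"],
            tables["s2"],
            min_copies=config.divergence.get("min_copies", 100),
            p_cutoff=config.divergence.get("p_cutoff", 0.01),
        )
        ddir = out / "divergence"
        ddir.mkdir(exist_ok=True)
        result.per_lineage.to_csv(ddir / "divergence.tsv", sep="\t", index=False)
        with open(ddir / "odds_summary.json", "w") as fh:
            json.dump(result.summary(), fh, indent=1)
        manifest["stages"]["diverge"] = result.summary()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
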