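"""End-to-end orchestration: simulate/ingest -> encode -> scan -> condition -> explain -> contacts.

A run is driven by a :class:`RunConfig` (built from a YAML file or keyword
arguments); every enabled stage reads the previous stage's tables from the
output directory, so stages can be toggled or re-run individually. A manifest
records the config echo, package version, SHA-256 hashes of all inputs and
outputs and per-stage row counts; deterministic stages reproduce byte-
identical outputs under an identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import qq_lambda, scan
from .conditional import conditional_scan_all
from .contacts import contact_frequency, overlay
from .encoding import (
    AlleleTranslationTable,
    CohortGenotypes,
    DosageMatrix,
    encode_allele_dosage,
    encode_site_dosage,
    filter_maf,
)
from .simulate import (
    EffectSpec,
    SimulationConfig,
    default_pool,
    generate_usage,
    sample_genotypes,
    synthesize_translation_table,
)
from .usage import UsageMatrix
from .variance import variance_report

logger = logging.getLogger(__name__)

STAGES = ("simulate", "encode", "associate", "condition", "explain", "contacts")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; thresholds default to the analysis values."""

    out_dir: str = "results/run"
    seed: int = 0
    phenotype_mode: str = "raw"
    maf: float = 0.05
    fdr: float = 0.05
    alpha: float = 0.05
    stages: list = field(default_factory=lambda: list(STAGES))
    # simulate stage
    simulation: dict = field(default_factory=dict)
    effects: list = field(default_factory=list)  # [variant_id, gene_id, beta] triples
    # real-data entry points (used when the simulate stage is disabled)
    genotypes_tsv: str | None = None
    translation_tsv: str | None = None
    usage_tsv: str | None = None
    usage_meta_tsv: str | None = None
    # contacts stage
    contact_records_tsv: str | None = None
    contact_roster_tsv: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        for name in ("fdr", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g", **kw)


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory). Stage outputs are TSV; summary counts per level and
    per stage are included in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    enabled = [s for s in STAGES if s in config.stages]

    genotypes = table = usage = None
    dosage_by_level: dict[str, DosageMatrix] = {}
    assoc = None
    signals = None

    if "simulate" in enabled:
        t = time.time()
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        pool = default_pool(seed=config.seed)
        genotypes = sample_genotypes(pool, sim.n_individuals, seed=config.seed + 1)
        table = synthesize_translation_table(pool, seed=config.seed + 2)
        # effects refer to encoded variants, so encode before planting
        aa = filter_maf(encode_site_dosage(genotypes, table, "amino_acid"), config.maf)
        effects = EffectSpec([tuple(e) for e in config.effects])
        usage, truth = generate_usage(genotypes, aa, effects, sim)
        genotypes.to_tsv(out / "genotypes.tsv")
        table.to_tsv(out / "translation.tsv")
        usage.to_tsv(out / "usage.tsv", out / "usage_meta.tsv")
        (out / "ground_truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
        manifest["stages"]["simulate"] = {
            "n_individuals": sim.n_individuals,
            "n_genes": sim.n_target_genes + sim.n_control_genes,
            "seconds": round(time.time() - t, 3),
        }
    else:
        if config.genotypes_tsv:
            genotypes = CohortGenotypes.from_tsv(config.genotypes_tsv)
        if config.translation_tsv:
            table = AlleleTranslationTable.from_tsv(config.translation_tsv)
        if config.usage_tsv:
            usage = UsageMatrix.from_tsv(config.usage_tsv, config.usage_meta_tsv)

    if "encode" in enabled:
        t = time.time()
        if genotypes is None:
            raise ValueError("encode stage needs genotypes (simulate stage or genotypes_tsv)")
        dosage_by_level["allele"] = filter_maf(encode_allele_dosage(genotypes), config.maf)
        if table is not None:
            for level in ("snp", "amino_acid"):
                dosage_by_level[level] = filter_maf(
                    encode_site_dosage(genotypes, table, level), config.maf
                )
        for level, dm in dosage_by_level.items():
            dm.to_tsv(out / f"dosage_{level}.tsv", out / f"dosage_{level}_meta.tsv")
        manifest["stages"]["encode"] = {
            **{f"n_variants_{lvl}": dm.n_variants for lvl, dm in dosage_by_level.items()},
            "seconds": round(time.time() - t, 3),
        }

    def _ensure_dosages() -> None:
        if not dosage_by_level:
            for level in ("allele", "snp", "amino_acid"):
                p = out / f"dosage_{level}.tsv"
                if p.exists():
                    dosage_by_level[level] = DosageMatrix.from_tsv(p, out / f"dosage_{level}_meta.tsv")
        if not dosage_by_level:
            raise ValueError("no dosage matrices available; run the encode stage first")

    if "associate" in enabled:
        t = time.time()
        if usage is None:
            raise ValueError("associate stage needs usage (simulate stage or usage_tsv)")
        _ensure_dosages()
        frames = []
        inflation = {}
        for level, dm in dosage_by_level.items():
            part = scan(usage, dm, phenotype_mode=config.phenotype_mode, fdr_threshold=config.fdr)
            frames.append(part)
            rep = qq_lambda(part["p_value"].to_numpy(), seed=config.seed)
            inflation[level] = rep.to_json_dict()
            _write(rep.qq, out / f"qq_{level}.tsv", index=False)
        assoc = pd.concat(frames, ignore_index=True)
        _write(assoc, out / "associations.tsv", index=False)
        (out / "inflation.json").write_text(json.dumps(inflation, indent=1))
        manifest["stages"]["associate"] = {
            "n_tests": int(len(assoc)),
            "n_significant_per_level": {
                lvl: int(g["significant"].sum()) for lvl, g in assoc.groupby("level")
            },
            "n_significant_variants_per_level": {
                lvl: int(g.loc[g["significant"], "variant_id"].nunique())
                for lvl, g in assoc.groupby("level")
            },
            "seconds": round(time.time() - t, 3),
        }

    if "condition" in enabled:
        t = time.time()
        if assoc is None:
            assoc = pd.read_csv(out / "associations.tsv", sep="\t")
        if usage is None:
            raise ValueError("condition stage needs usage")
        _ensure_dosages()
        level = "amino_acid" if "amino_acid" in dosage_by_level else next(iter(dosage_by_level))
        signals = conditional_scan_all(
            usage.values, dosage_by_level[level], assoc, alpha=config.alpha, level=level
        )
        _write(signals, out / "conditional_signals.tsv", index=False)
        manifest["stages"]["condition"] = {
            "n_genes_with_signals": int(signals["gene_id"].nunique()) if len(signals) else 0,
            "n_signals": int(len(signals)),
            "seconds": round(time.time() - t, 3),
        }

    if "explain" in enabled:
        t = time.time()
        if signals is None:
            signals = pd.read_csv(out / "conditional_signals.tsv", sep="\t")
        if usage is None:
            raise ValueError("explain stage needs usage")
        _ensure_dosages()
        level = "amino_acid" if "amino_acid" in dosage_by_level else next(iter(dosage_by_level))
        report = variance_report(usage.values, signals, dosage_by_level[level], config.fdr)
        _write(report, out / "variance_explained.tsv", index=False)
        manifest["stages"]["explain"] = {
            "n_genes": int(len(report)),
            "seconds": round(time.time() - t, 3),
        }

    if "contacts" in enabled and config.contact_records_tsv and config.contact_roster_tsv:
        t = time.time()
        records = pd.read_csv(config.contact_records_tsv, sep="\t")
        roster = pd.read_csv(config.contact_roster_tsv, sep="\t")
        profile = contact_frequency(records, roster)
        _write(profile, out / "contact_profile.tsv", index=False)
        if assoc is None and (out / "associations.tsv").exists():
            assoc = pd.read_csv(out / "associations.tsv", sep="\t")
        ol = overlay(assoc if assoc is not None else pd.DataFrame(), profile)
        _write(ol, out / "contact_overlay.tsv", index=False)
        manifest["stages"]["contacts"] = {
            "n_profile_rows": int(len(profile)),
            "n_overlay_rows": int(len(ol)),
            "seconds": round(time.time() - t, 3),
        }

    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
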