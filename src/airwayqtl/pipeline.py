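"""End-to-end pipeline: simulate -> PC150 phenotypes -> genome scan -> stats.

Each stage reads/writes plain delimited text (CSV) plus JSON results, so a
run directory is fully inspectable. A manifest records the effective
config, the seed, per-output SHA-256 checksums and per-stage counts;
reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .genome import FounderDosageMap, GenomeMap
from .phenotype import PC150Phenotyper, boxcox_profile
from .scan import HaplotypeScan
from .stats import correlation_matrix, strain_anova, strain_summaries

log = logging.getLogger("airwayqtl")

STAGES = ("simulate", "pc150", "scan", "stats")

#: founder-effect patterns (centred at build time) used by the fixtures:
#: one founder's haplotype elevated against the other seven
def one_founder_pattern(founder_index: int, size: float = 1.0) -> tuple[float, ...]:
    e = np.zeros(8)
    e[founder_index] = size
    return tuple(float(v) for v in e - e.mean())


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    seed: int = 0
    # population
    n_mice: int = 150
    chromosomes: list = field(
        default_factory=lambda: [["1", 100.0], ["2", 100.0], ["3", 100.0],
                                 ["4", 100.0], ["5", 100.0]]
    )
    markers_per_chromosome: int = 100
    switch_rate: float = sim.DEFAULT_SWITCH_RATE
    heterozygosity: float = sim.DEFAULT_HETEROZYGOSITY
    # QTL architecture: list of dicts accepted by simulate.QTLSpec
    qtls: list = field(
        default_factory=lambda: [
            {"chrom": "4", "pos_mb": 50.0, "effects": list(one_founder_pattern(1)),
             "target": "baseline", "target_variance": 0.20},
            {"chrom": "5", "pos_mb": 50.0, "effects": list(one_founder_pattern(1)),
             "target": "final", "target_variance": 0.21},
        ]
    )
    ln_noise_sd: float = sim.DEFAULT_LN_NOISE_SD
    baseline_final_rho: float = sim.DEFAULT_BASELINE_FINAL_RHO
    # curves
    doses: list = field(default_factory=lambda: list(sim.DEFAULT_DOSES))
    curve_noise_sd: float = sim.DEFAULT_CURVE_NOISE_SD
    removal_threshold: float = sim.DEFAULT_REMOVAL_THRESHOLD
    # phenotype derivation
    pc_threshold: float = 150.0
    extrapolation_cap: float = 2.0
    # scan
    n_perm: int = 200
    quantiles: list = field(default_factory=lambda: [0.95, 0.80])
    homozygote_cutoff: float = 1.8
    scan_columns: list = field(default_factory=lambda: ["ln_baseline", "ln_final", "delta"])
    # orchestration
    stages: list = field(default_factory=lambda: list(STAGES))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent, reproducible sub-seeds for each randomised stage."""
    state = np.random.SeedSequence(seed).generate_state(5, dtype=np.uint64)
    names = ("mosaics", "phenotypes", "curves", "biomarkers", "perms")
    return {k: int(v % (2**31)) for k, v in zip(names, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixtures(size: str = "tiny", seed: int = 0) -> RunConfig:
    """Packaged example configurations.

    ``tiny``: 20 mice, one chromosome, 50 markers — runs in seconds and
    backs the test suite. ``demo``: 150 mice, five chromosomes, 500
    markers, one baseline-phenotype QTL and one final-phenotype QTL on
    different chromosomes, emulating a study in which pre- and
    post-allergen responsiveness map to distinct loci.
    """
    if size == "tiny":
        return RunConfig(
            seed=seed,
            n_mice=20,
            chromosomes=[["1", 100.0]],
            markers_per_chromosome=50,
            qtls=[{"chrom": "1", "pos_mb": 50.0,
                   "effects": list(one_founder_pattern(1)),
                   "target": "final", "target_variance": 0.35}],
            n_perm=100,
        )
    if size == "demo":
        return RunConfig(seed=seed)
    raise ValueError(f"unknown fixture size {size!r} (use 'tiny' or 'demo')")


def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate population, curves and biomarkers; write the study inputs."""
    seeds = _stage_seeds(config.seed)
    gmap = GenomeMap.uniform(
        [tuple(c) for c in config.chromosomes], config.markers_per_chromosome
    )
    pop = sim.simulate_mosaics(
        config.n_mice, gmap, config.switch_rate, config.heterozygosity,
        seed=seeds["mosaics"],
    )
    dosage = sim.mosaics_to_dosage(pop)
    qtls = [sim.QTLSpec(**q) for q in config.qtls]
    truth = sim.simulate_phenotypes(
        dosage, qtls, seed=seeds["phenotypes"],
        ln_noise_sd=config.ln_noise_sd,
        baseline_final_rho=config.baseline_final_rho,
    )
    penh = sim.simulate_penh_curves(
        truth.latent, doses=tuple(config.doses),
        curve_noise_sd=config.curve_noise_sd,
        removal_threshold=config.removal_threshold,
        seed=seeds["curves"],
    )
    biomarkers = sim.simulate_biomarkers(
        np.exp(truth.latent["ln_pc150_final"].to_numpy()),
        truth.latent["mouse_id"].tolist(),
        seed=seeds["biomarkers"],
    )
    penh.to_csv(outdir / "penh.csv", index=False)
    dosage.to_csv(outdir / "dosage.csv")
    biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    truth.to_json(outdir / "truth.json")
    log.info("simulate: %d mice, %d markers", config.n_mice, dosage.n_markers)
    return {
        "n_mice": config.n_mice,
        "n_markers": int(dosage.n_markers),
        "outputs": ["penh.csv", "dosage.csv", "biomarkers.csv", "truth.json"],
    }


def pc150_stage(config: RunConfig, outdir: Path) -> dict:
    """Derive per-mouse PC150 phenotypes from the Penh table."""
    penh_path = outdir / "penh.csv"
    if not penh_path.exists():
        raise FileNotFoundError(f"pc150 stage needs {penh_path} (run the simulate stage "
                                "or provide a Penh table)")
    penh = pd.read_csv(penh_path)
    phenotyper = PC150Phenotyper(
        threshold=config.pc_threshold, extrapolation_cap=config.extrapolation_cap
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        table = phenotyper.fit_transform(penh)
    table.to_csv(outdir / "phenotypes.csv", index=False)
    log.info("pc150: %d mice, %d excluded", phenotyper.n_mice_, phenotyper.n_excluded_)
    return {
        "n_mice": phenotyper.n_mice_,
        "n_excluded": phenotyper.n_excluded_,
        "exclusion_reasons": phenotyper.exclusion_reasons_,
        "outputs": ["phenotypes.csv"],
    }


def scan_stage(config: RunConfig, outdir: Path) -> dict:
    """Genome scans of the configured phenotype columns."""
    pheno_path = outdir / "phenotypes.csv"
    dosage_path = outdir / "dosage.csv"
    for p in (pheno_path, dosage_path):
        if not p.exists():
            raise FileNotFoundError(f"scan stage needs {p}")
    phenotypes = pd.read_csv(pheno_path)
    dosage = FounderDosageMap.from_csv(dosage_path)
    order = {m: i for i, m in enumerate(dosage.mouse_ids)}
    phenotypes = phenotypes.sort_values("mouse_id", key=lambda s: s.map(order))
    results = {}
    outputs = []
    for column in config.scan_columns:
        y = phenotypes[column].to_numpy(dtype=float)
        est = HaplotypeScan(
            n_permutations=config.n_perm,
            quantiles=tuple(config.quantiles),
            homozygote_cutoff=config.homozygote_cutoff,
            random_state=_stage_seeds(config.seed)["perms"],
        )
        est.fit(dosage, y)
        results[column] = est.result()
        trace = f"scan_{column}.csv"
        est.lod_table().to_csv(outdir / trace, index=False)
        outputs.append(trace)
        log.info("scan %s: peak LOD %.2f on chr %s", column, est.peak_lod_,
                 est.peak_marker_["chrom"])
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1)
    outputs.append("results.json")
    return {"phenotypes_scanned": list(config.scan_columns), "outputs": outputs}


def stats_stage(config: RunConfig, outdir: Path) -> dict:
    """Population summaries, transformation diagnostics and correlations."""
    pheno_path = outdir / "phenotypes.csv"
    if not pheno_path.exists():
        raise FileNotFoundError(f"stats stage needs {pheno_path}")
    phenotypes = pd.read_csv(pheno_path)
    strain_path = outdir / "strains.csv"
    if strain_path.exists():
        strains = pd.read_csv(strain_path).set_index("mouse_id")["strain"]
    else:
        strains = pd.Series("preCC", index=phenotypes["mouse_id"].to_numpy())
    summaries = strain_summaries(phenotypes, strains)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    outputs = ["summaries.csv"]
    counts = {"n_mice": len(phenotypes)}

    ok = phenotypes[phenotypes["status"] == "ok"]
    diag = {}
    for col in ("pc150_baseline", "pc150_final"):
        prof = boxcox_profile(ok[col].to_numpy())
        diag[col] = {"ci": prof["ci"], "suggested": prof["suggested"]}
    if strains.nunique() > 1:
        grouped = {
            s: np.log(g["pc150_final"].dropna().to_numpy())
            for s, g in ok.assign(strain=ok["mouse_id"].map(strains)).groupby("strain")
        }
        F, p = strain_anova(grouped)
        diag["anova_ln_final"] = {"F": F, "p": p}

    bio_path = outdir / "biomarkers.csv"
    if bio_path.exists():
        corr = correlation_matrix(ok, pd.read_csv(bio_path))
        corr.to_csv(outdir / "correlations.csv", index=False)
        outputs.append("correlations.csv")
        counts["n_correlations"] = len(corr)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(diag, fh, indent=1)
    outputs.append("stats.json")
    return {**counts, "outputs": outputs}


_STAGE_FUNCS = {
    "simulate": simulate_stage,
    "pc150": pc150_stage,
    "scan": scan_stage,
    "stats": stats_stage,
}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the enabled stages in order and write a manifest.

    Returns the manifest dict. A stage failure is recorded in the
    manifest (with partial outputs retained on disk) and re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    try:
        for stage in config.stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}")
            info = _STAGE_FUNCS[stage](config, outdir)
            manifest["stages"][stage] = {"status": "ok", **info}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outdir)
        raise
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["checksums"][f.name] = _sha256(f)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
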