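"""End-to-end orchestration: simulate -> qc -> grm -> index -> gblup -> evaluate.

Each stage writes into its own subdirectory of the run directory together
with a JSON manifest (parameters, input-file SHA-256 hashes, seeds), so any
report can be traced to its exact inputs.  A full rerun with the same config
and seeds is bit-identical except for timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import gblup as gb
from . import index as ix
from . import io_plink, qc, study
from .grm import compute_grm, compute_pcs, write_grm_bin, write_grm_csv
from .simulate import SimConfig, simulate_population, write_population


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Schema violation in input data (exit code 3 at the CLI)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


#: Raw trainer-category counts on the original scales for the reference
#: colony of 844 dogs (used to build the standardization-check fixture).
RAW_CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "pace": {"Fast": 2, "Above average": 42, "High average": 205,
             "Average": 551, "Less than average": 44},
    "distraction": {"High": 20, "Above average": 364, "Average": 412,
                    "Less than average": 48},
    "pull": {"Hard": 3, "Above average": 46, "Average": 511,
             "Defined average": 233, "Less than average": 51},
    "neck": {"Hard": 9, "Above average": 264, "Average": 496,
             "Less than average": 69, "Easy": 6},
    "rating": {"5": 8, "4+": 10, "4": 174, "4-": 11, "3+": 305,
               "3": 282, "3-": 32, "2+": 22},
    "soundness": {"Sound": 262, "Above average": 484, "Average": 92,
                  "Less than average": 6},
}

#: Expected condensed score-level counts implied by the map above.
CONDENSED_SCORE_COUNTS: dict[str, dict[int, int]] = {
    "pace": {2: 249, 1: 551, 0: 44},
    "distraction": {1: 384, 0: 460},
    "pull": {2: 49, 1: 744, 0: 51},
    "neck": {2: 273, 1: 496, 0: 75},
    "rating": {7: 8, 6: 10, 5: 174, 4: 11, 3: 305, 2: 282, 1: 32, 0: 22},
    "soundness": {2: 262, 1: 484, 0: 98},
}

_ORDINAL_TRAITS = ("pace", "pull", "neck", "rating", "soundness", "trainability",
                   "dental_count", "ocular_count", "dermal_count", "health_count")
_CONTINUOUS_TRAITS = ("behavior_score", "health_score", "total_score",
                      "parent_total_score", "parent_health_score", "parent_behavior_score")


def trait_kind(name: str) -> str:
    """Metric family for a trait: binary, ordinal or continuous."""
    if name in _ORDINAL_TRAITS:
        return "ordinal"
    if name in _CONTINUOUS_TRAITS or name.endswith("_score"):
        return "continuous"
    return "binary"  # success, distraction(condensed), and health diagnoses


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: ["simulate", "qc", "grm", "index",
                                                  "gblup", "evaluate"])
    genotype_prefix: str | None = None
    pheno_csv: str | None = None
    sim: dict = field(default_factory=dict)
    qc_thresholds: dict = field(default_factory=dict)
    grm_method: str = "vanraden1"
    n_pcs: int = 3
    trait_config: str | None = None
    traits: list | str = "all"
    k_folds: int = 5
    fixed_effects: list = field(default_factory=lambda: ["birth_year", "pc1", "pc2", "pc3"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as e:
            raise ConfigError(f"cannot read run config {path}: {e}") from e
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown run-config keys: {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(stage_dir: Path, stage: str, params: dict, inputs: list) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def validate_pheno(pheno: pd.DataFrame, smap=None) -> None:
    """Schema check: required columns present, behavior labels known."""
    for col in ("id",):
        if col not in pheno.columns:
            raise DataError(f"phenotype table missing required column {col!r}")
    smap = ix.STANDARDIZATION_MAP if smap is None else smap
    for t in ix.BEHAVIOR_TRAITS:
        if t in pheno.columns and pheno[t].dtype == object:
            for i, v in pheno[t].items():
                try:
                    ix.standardize_trait(v, smap, t)
                except ix.UnknownLabelError as e:
                    raise DataError(f"row {i}, column {t!r}: {e}") from e


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = None
    pheno = None
    grm = None
    sim_truth = None

    geno_prefix = config.genotype_prefix
    pheno_path = config.pheno_csv

    for stage in config.stages:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            if stage == "simulate":
                sim_kwargs = dict(config.sim)
                base = study.default_study_config(seed=config.seed)
                params = {f.name: getattr(base, f.name) for f in dataclasses.fields(SimConfig)}
                params.update(sim_kwargs)
                params["seed"] = sim_kwargs.get("seed", config.seed)
                sim_config = SimConfig(**params)
                pop = simulate_population(sim_config)
                write_population(pop, stage_dir / "geno", fmt="bed")
                geno_prefix = str(stage_dir / "geno")
                pheno_path = str(stage_dir / "geno.pheno.csv")
                sim_truth = pop
                _manifest(stage_dir, stage,
                          {k: str(v) for k, v in sim_kwargs.items()} | {"seed": params["seed"]},
                          [])
            elif stage == "qc":
                if geno is None:
                    if geno_prefix is None:
                        raise ConfigError("qc stage needs a genotype prefix")
                    geno = io_plink.read_genotypes(geno_prefix)
                thresholds = qc.QcThresholds(**config.qc_thresholds)
                geno, report = qc.run_qc(geno, thresholds)
                io_plink.write_bed(geno, stage_dir / "filtered")
                (stage_dir / "qc_report.json").write_text(report.to_json())
                (stage_dir / "qc_report.log").write_text(report.summary() + "\n")
                _manifest(stage_dir, stage, dataclasses.asdict(thresholds),
                          [Path(geno_prefix).with_suffix(s) for s in (".bed", ".ped")])
            elif stage == "grm":
                if geno is None:
                    if geno_prefix is None:
                        raise ConfigError("grm stage needs genotypes")
                    geno = io_plink.read_genotypes(geno_prefix)
                grm = compute_grm(geno, method=config.grm_method)
                write_grm_bin(grm, stage_dir / "grm")
                if grm.n <= 2000:
                    write_grm_csv(grm, stage_dir / "grm.csv")
                pcs = compute_pcs(grm, config.n_pcs)
                pd.DataFrame(pcs, index=grm.ids,
                             columns=[f"pc{j + 1}" for j in range(config.n_pcs)]
                             ).to_csv(stage_dir / "pcs.csv")
                _manifest(stage_dir, stage,
                          {"method": config.grm_method, "n_pcs": config.n_pcs,
                           "n_snps_used": grm.n_snps_used}, [])
            elif stage == "index":
                if pheno is None:
                    if pheno_path is None:
                        raise ConfigError("index stage needs a phenotype CSV")
                    pheno = pd.read_csv(pheno_path)
                validate_pheno(pheno)
                if config.trait_config:
                    specs, smap, weights = ix.load_trait_config(config.trait_config)
                else:
                    specs, smap, weights = ix.load_trait_config()
                pheno = ix.score_table(pheno, specs, weights, smap)
                pheno.to_csv(stage_dir / "scored.csv", index=False)
                pheno_path = str(stage_dir / "scored.csv")
                _manifest(stage_dir, stage,
                          {"w_health": weights.w_health, "w_behavior": weights.w_behavior},
                          [config.trait_config] if config.trait_config else [])
            elif stage in ("gblup", "evaluate"):
                if grm is None:
                    raise ConfigError(f"{stage} stage needs a GRM (enable the grm stage)")
                if pheno is None:
                    if pheno_path is None:
                        raise ConfigError(f"{stage} stage needs phenotypes")
                    pheno = pd.read_csv(pheno_path)
                tbl = pheno.set_index("id", drop=False)
                tbl.index = tbl.index.astype(str)
                traits = config.traits
                if traits == "all":
                    skip = {"id", "sire", "dam", "birth_year"}
                    traits = [c for c in tbl.columns
                              if c not in skip and pd.api.types.is_numeric_dtype(tbl[c])
                              and not tbl[c].isna().any()]
                if stage == "gblup":
                    tbl_pc = _with_pcs(tbl, grm, config.n_pcs)
                    rows = []
                    for t in traits:
                        fit = gb.fit_gblup(tbl_pc, grm, t, fixed_effects=config.fixed_effects)
                        rows.append({"trait": t, "sigma2_g": fit.vc.sigma2_g,
                                     "sigma2_e": fit.vc.sigma2_e,
                                     "pseudo_h2": fit.vc.pseudo_h2,
                                     "log_reml": fit.vc.log_reml})
                        pd.DataFrame({"id": fit.ids, "gebv": fit.gebv,
                                      "fitted": fit.fitted}).to_csv(
                            stage_dir / f"gebv_{t}.csv", index=False)
                    pd.DataFrame(rows).to_csv(stage_dir / "variance_components.csv", index=False)
                    _manifest(stage_dir, stage, {"traits": list(traits)}, [pheno_path])
                else:
                    folds = ev.make_folds(grm.ids, k=config.k_folds, seed=config.seed)
                    tbl2 = _with_pcs(tbl, grm, config.n_pcs)
                    reports = []
                    per_fold = {}
                    for t in traits:
                        rep = ev.evaluate_trait(t, tbl2, grm, trait_kind(t),
                                                fixed_effects=config.fixed_effects,
                                                folds=folds)
                        reports.append(rep)
                        per_fold[t] = rep.per_fold
                    ev.report_frame(reports).to_csv(stage_dir / "report.csv", index=False)
                    with open(stage_dir / "per_fold.json", "w") as fh:
                        json.dump(per_fold, fh, indent=2, default=float)
                    _manifest(stage_dir, stage,
                              {"k": config.k_folds, "seed": config.seed,
                               "traits": list(traits)}, [pheno_path])
            else:
                raise ConfigError(f"unknown stage {stage!r}")
        except (ConfigError, DataError):
            raise
        except Exception as e:  # halt with a stage-named error
            raise StageError(stage, e) from e
    return out


def _with_pcs(tbl: pd.DataFrame, grm, n_pcs: int) -> pd.DataFrame:
    tbl = tbl.copy()
    if n_pcs > 0 and "pc1" not in tbl.columns:
        pcs = compute_pcs(grm, n_pcs)
        pcdf = pd.DataFrame(pcs, index=grm.ids,
                            columns=[f"pc{j + 1}" for j in range(n_pcs)])
        tbl = tbl.join(pcdf)
    return tbl


def make_fixture(name: str, seed: int = 0):
    """Deterministic tiny datasets with known truths, for tests and demos.

    * ``"trio"``: 10 parent-offspring trios (both parents fully phenotyped).
    * ``"null"``: every trait heritability 0.
    * ``"behavior-counts"``: an 844-row table of raw behavior category labels
      whose per-category counts equal the reference colony's exactly.
    """
    from .simulate import SimTraitSpec

    if name == "behavior-counts":
        rng = np.random.default_rng(seed)
        cols = {}
        for trait, counts in RAW_CATEGORY_COUNTS.items():
            labels = np.repeat([lab for lab in counts], [counts[lab] for lab in counts])
            rng.shuffle(labels)
            cols[trait] = labels
        n = len(next(iter(cols.values())))
        df = pd.DataFrame(cols)
        df.insert(0, "id", [f"D{i:04d}" for i in range(n)])
        return df

    traits = [
        SimTraitSpec("trainability", "ordinal", 0.0 if name == "null" else 0.4,
                     (0.05, 0.20, 0.40, 0.25, 0.10)),
        SimTraitSpec("atopic_dermatitis", "binary", 0.0 if name == "null" else 0.3, 0.2),
        SimTraitSpec("pace", "ordinal", 0.0 if name == "null" else 0.2,
                     (44 / 844, 551 / 844, 249 / 844)),
    ]
    if name == "trio":
        config = SimConfig(n_founders=20, n_offspring=10, n_trio_offspring=10,
                           n_snps=200, n_causal_per_trait=50, trait_specs=traits,
                           success_weights={"trainability": 0.53}, seed=seed)
    elif name == "null":
        config = SimConfig(n_founders=30, n_offspring=20, n_trio_offspring=10,
                           n_snps=200, n_causal_per_trait=50, trait_specs=traits,
                           success_weights={}, seed=seed)
    else:
        raise ConfigError(f"unknown fixture {name!r}")
    return simulate_population(config)
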