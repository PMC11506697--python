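"""End-to-end runs: simulate -> preprocess -> fit -> stage -> associate.

A run is driven by a `RunConfig`, writes every artifact into one output
directory, and finishes with a manifest recording the configuration and a
SHA-256 hash of each file, so that re-running with the same configuration
and seed is verifiably byte-identical. Subgroup runs (HS-only / NL-only)
are row filters on the patient table; the healthy-control normative model
is fitted once per dataset and shared across subgroups.
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

from .cohort import CohortConfig, generate_cohort, save_cohort, load_cohort
from .model import SubtypeStageModel, select_n_subtypes
from .preprocess import CovariateNormalizer, lateralize
from .stats import build_association_report

__all__ = ["RunConfig", "run_pipeline", "sha256_file"]

log = logging.getLogger("tractstage")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON serialisable)."""

    output_dir: str = "tractstage_run"
    cohort_csv: str | None = None       # None -> simulate a cohort
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides
    subgroup: str = "all"               # all | HS | NL
    n_subtypes: int | str = 1           # int, or "auto" for CVIC selection
    max_subtypes: int = 3
    folds: int = 10
    thresholds: tuple = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    sigma: float = 1.0
    n_starts: int = 25
    mcmc_iter: int = 100_000
    burn_in: float = 0.1
    max_greedy_passes: int | None = None
    cv_n_starts: int = 2
    cv_mcmc_iter: int = 0
    cv_max_greedy_passes: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.subgroup not in ("all", "HS", "NL"):
            raise ValueError(f"subgroup must be all/HS/NL, got "
                             f"{self.subgroup!r}")
        if self.n_subtypes != "auto" and (
                not isinstance(self.n_subtypes, int) or self.n_subtypes < 1):
            raise ValueError("n_subtypes must be a positive int or 'auto'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, index=index, float_format="%.12g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and return the manifest dict."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # ------------------------------------------------------------ cohort
    if cfg.cohort_csv is None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        ccfg = CohortConfig.from_dict(sim)
        table, gt = generate_cohort(ccfg)
        save_cohort(table, out / "cohort.csv")
        gt.save(out / "ground_truth.json")
        artifacts["cohort"] = out / "cohort.csv"
        artifacts["ground_truth"] = out / "ground_truth.json"
        log.info("simulated cohort: %d HC, %d TLE", ccfg.n_hc, ccfg.n_patients)
    else:
        table = load_cohort(cfg.cohort_csv)

    hc = table[table["group"] == "HC"]
    patients = table[table["group"] == "TLE"]

    # -------------------------------------------------------- preprocess
    norm = CovariateNormalizer().fit(hc)
    norm.save(out / "covariate_model.json")
    artifacts["covariate_model"] = out / "covariate_model.json"
    z = norm.transform(patients)
    zmat = lateralize(z, patients)
    if cfg.subgroup != "all":
        keep = patients.loc[patients["etiology"] == cfg.subgroup,
                            "subject_id"]
        zmat = zmat.loc[zmat.index.isin(set(keep))]
        patients = patients[patients["etiology"] == cfg.subgroup]
        log.info("subgroup %s: %d patients analyzed", cfg.subgroup, len(zmat))
    _write_csv(zmat.reset_index(), out / "zmatrix.csv")
    artifacts["zmatrix"] = out / "zmatrix.csv"
    log.info("abnormality matrix: %d patients x %d ROIs", *zmat.shape)

    # --------------------------------------------------------------- fit
    rng = np.random.default_rng(cfg.seed)
    cvic = None
    n_subtypes = cfg.n_subtypes
    if n_subtypes == "auto":
        chosen, cvic = select_n_subtypes(
            zmat, cfg.max_subtypes, folds=cfg.folds,
            seed=int(rng.integers(2**31)),
            thresholds=cfg.thresholds, z_max=cfg.z_max, sigma=cfg.sigma,
            n_starts=cfg.cv_n_starts, mcmc_iter=cfg.cv_mcmc_iter,
            max_greedy_passes=cfg.cv_max_greedy_passes)
        n_subtypes = chosen
        log.info("CVIC selected %d subtype(s): %s", chosen, cvic)

    model = SubtypeStageModel(
        n_subtypes=n_subtypes, thresholds=cfg.thresholds, z_max=cfg.z_max,
        sigma=cfg.sigma, n_starts=cfg.n_starts, mcmc_iter=cfg.mcmc_iter,
        burn_in=cfg.burn_in, max_greedy_passes=cfg.max_greedy_passes,
        random_state=int(rng.integers(2**31)))
    model.fit(zmat)
    for res in model.mcmc_:
        if res is not None:
            log.info("MCMC acceptance %.3f, %d invalid proposals",
                     res.acceptance_rate, res.n_invalid_proposals)
    log.info("greedy start/final log-likelihoods: %s",
             [(round(a, 1), round(b, 1)) for a, b in model.greedy_start_lls_])

    model_doc = {
        "event_labels": model.event_set_.event_labels(),
        "thresholds": list(cfg.thresholds), "z_max": cfg.z_max,
        "sigma": cfg.sigma, "n_subtypes": int(len(model.sequences_)),
        "sequences": [model.sequence_labels(c)
                      for c in range(len(model.sequences_))],
        "sequence_orders": [s.tolist() for s in model.sequences_],
        "fractions": model.fractions_.tolist(),
        "log_likelihood": model.log_likelihood_,
        "cvic": ({str(k): v for k, v in cvic.items()} if cvic else None),
        "subtype_similarity": model.subtype_similarity().tolist(),
        "mcmc_acceptance": [r.acceptance_rate if r else None
                            for r in model.mcmc_],
        "config": {"seed": cfg.seed, "n_starts": cfg.n_starts,
                   "mcmc_iter": cfg.mcmc_iter, "subgroup": cfg.subgroup},
    }
    with open(out / "model.json", "w") as fh:
        json.dump(model_doc, fh, indent=1)
    artifacts["model"] = out / "model.json"

    if cfg.mcmc_iter > 0:
        for c in range(len(model.sequences_)):
            dens = model.positional_density(c)
            # rows in ML-sequence order, as the figure convention
            ml = model.sequences_[c]
            labels = model.event_set_.event_labels()
            dd = pd.DataFrame(dens[ml], index=[labels[e] for e in ml],
                              columns=[str(p + 1)
                                       for p in range(dens.shape[1])])
            name = (f"positional_density_subtype{c}.csv"
                    if len(model.sequences_) > 1 else "positional_density.csv")
            _write_csv(dd, out / name, index=True)
            artifacts[f"positional_density_{c}"] = out / name

    # ------------------------------------------------------------- stage
    stages = model.predict_stages(zmat)
    _write_csv(stages.to_frame(), out / "stages.csv")
    artifacts["stages"] = out / "stages.csv"

    # --------------------------------------------------------- associate
    report = build_association_report(stages, patients)
    report.save(out / "association_report.csv",
                out / "association_report.txt")
    artifacts["association_report"] = out / "association_report.csv"
    artifacts["association_report_text"] = out / "association_report.txt"

    # ---------------------------------------------------------- manifest
    manifest = {
        "config": cfg.to_dict(),
        "n_patients_analyzed": int(zmat.shape[0]),
        "artifacts": {k: {"path": str(p.name), "sha256": sha256_file(p)}
                      for k, p in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    missing = [k for k, p in artifacts.items() if not p.exists()]
    if missing:
        raise RuntimeError(f"manifest incomplete; missing artifacts {missing}")
    return manifest
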