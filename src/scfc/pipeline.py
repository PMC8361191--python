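"""End-to-end orchestration from a single YAML config.

``run_pipeline`` executes simulate -> couple -> reliability -> glm ->
heritability -> netstats (each stage can be toggled), writing every
intermediate table, a log and a machine-readable ``summary.json`` into
the output directory.  Every output table carries a leading comment
naming the config hash and seed that produced it, and re-running with
the same config reproduces all outputs.

Synthetic runs generate the cohort on the fly; alternatively
``parcellation/sc_dir/fc_dir/cohort/pedigree`` paths point at user data
in the formats of :mod:`scfc.io`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling as cp
from . import io as scio
from .atlas import default_parcellation
from .association import build_design, fit_regional_glm
from .datatypes import Pedigree, PhenotypeTable
from .heritability import regional_heritability
from .netstats import network_summary, permutation_p_t
from .reliability import agreement_correlation, bland_altman
from .simulate import (
    FamilyComposition,
    TrueVariances,
    generate_covariates,
    generate_pedigree,
    regional_coupling_profile,
    simulate_ace_phenotypes,
    simulate_subject_connectomes,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "scfc_run"
    seed: int = 0
    # synthetic-data settings
    n_regions: int = 50
    n_mz_pairs: int = 25
    n_dz_pairs: int = 13
    n_full_sibs: int = 98
    n_singletons: int = 26
    n_fc_measurements: int = 4
    coupling_mean: float = 0.25
    coupling_sd: float = 0.08
    sc_density: float = 0.35
    write_matrices: bool = False
    # user-data paths (override synthetic generation when set)
    parcellation: str | None = None
    sc_dir: str | None = None
    fc_dir: str | None = None
    cohort: str | None = None
    pedigree: str | None = None
    # stage toggles
    run_simulate: bool = True
    run_couple: bool = True
    run_reliability: bool = True
    run_glm: bool = True
    run_heritability: bool = True
    run_netstats: bool = True
    # analysis settings
    variants: tuple[str, ...] = ("whole_brain",)
    alpha: float = 0.05
    n_perm: int = 1000
    subgroup_filter: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not isinstance(cfg.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def filter_pedigree(pedigree: Pedigree, keep_ids) -> Pedigree:
    """Restrict a pedigree to a subject subset, repairing relationships.

    A twin whose co-twin is dropped becomes a full sibling if relatives
    remain in the family, else a singleton (matching how the kinship
    kernel treats the survivor).
    """
    keep = set(keep_ids)
    t = pedigree.table[pedigree.table["subject_id"].isin(keep)].copy()
    pair_counts = t[t["twin_pair_id"] != ""].groupby("twin_pair_id")[
        "subject_id"
    ].count()
    fam_counts = t.groupby("family_id")["subject_id"].count()
    orphan = t["twin_pair_id"].map(pair_counts).fillna(0) == 1
    alone = t["family_id"].map(fam_counts) == 1
    t.loc[orphan & ~alone, "relationship"] = "full_sibling"
    t.loc[orphan & ~alone, "twin_pair_id"] = ""
    t.loc[(orphan | (t["relationship"] != "singleton")) & alone, "relationship"] = (
        "singleton"
    )
    t.loc[alone, "twin_pair_id"] = ""
    return Pedigree(t.reset_index(drop=True))


class _Run:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.header = f"config_hash={config.config_hash()} seed={config.seed}"
        self.summary: dict = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
        }
        self.log_lines: list[str] = []

    def log(self, msg: str) -> None:
        self.log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def write_table(self, obj, name: str) -> None:
        scio.write_table(obj, self.out / name, header=self.header)

    def finish(self) -> None:
        with open(self.out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)
        (self.out / "log.txt").write_text("\n".join(self.log_lines) + "\n")


def _simulate_inputs(run: _Run):
    cfg = run.cfg
    parc = default_parcellation(cfg.n_regions)
    comp = FamilyComposition(
        cfg.n_mz_pairs, cfg.n_dz_pairs, cfg.n_full_sibs, cfg.n_singletons
    )
    pedigree = generate_pedigree(comp, seed=cfg.seed)
    cohort = generate_covariates(pedigree, seed=cfg.seed + 1)
    # subject-level coupling targets: heritable via an ACE draw on the
    # latent target, so downstream heritability has signal to find
    target_tbl = simulate_ace_phenotypes(
        pedigree,
        TrueVariances(0.5, 0.1, 0.3, 0.0),
        n_measurements=1,
        seed=cfg.seed + 2,
        column_name="target",
    ).table
    scale = target_tbl["target"].std()
    offsets = (
        cfg.coupling_sd * target_tbl["target"] / max(scale, 1e-9)
    ).to_numpy()
    # regional profile (network-structured map) + heritable subject offset
    profile = regional_coupling_profile(parc, seed=cfg.seed)
    profile = profile + (cfg.coupling_mean - profile.mean())
    rng = np.random.default_rng(cfg.seed + 3)
    connectomes = {}
    for i, sid in enumerate(pedigree.subject_ids):
        sc, fcs = simulate_subject_connectomes(
            parc,
            np.clip(profile + offsets[i], -0.9, 0.9),
            sc_density=cfg.sc_density,
            seed=int(rng.integers(2**31 - 1)),
            n_fc_measurements=cfg.n_fc_measurements,
            subject_id=sid,
        )
        connectomes[sid] = (sc, fcs)
    run.write_table(parc, "parcellation.tsv")
    run.write_table(pedigree, "pedigree.tsv")
    run.write_table(cohort, "cohort.tsv")
    if cfg.write_matrices:
        mat_dir = run.out / "connectomes"
        mat_dir.mkdir(exist_ok=True)
        for sid, (sc, fcs) in connectomes.items():
            scio.write_matrix(
                sc.matrix, mat_dir / scio.connectome_filename(sid, "SC", 1),
                header=run.header,
            )
            for j, fc in enumerate(fcs, start=1):
                scio.write_matrix(
                    fc.matrix, mat_dir / scio.connectome_filename(sid, "FC", j),
                    header=run.header,
                )
    run.log(
        f"simulated {pedigree.n_subjects} subjects, {parc.n_regions} regions, "
        f"{cfg.n_fc_measurements} FC measurements"
    )
    return parc, pedigree, cohort, connectomes


def _load_inputs(run: _Run):
    cfg = run.cfg
    parc = scio.read_parcellation(cfg.parcellation)
    pedigree = scio.read_pedigree(cfg.pedigree) if cfg.pedigree else None
    cohort = scio.read_cohort(cfg.cohort) if cfg.cohort else None
    connectomes = {}
    sc_dir, fc_dir = Path(cfg.sc_dir), Path(cfg.fc_dir)
    subjects = sorted({p.name.split("_")[0] for p in sc_dir.glob("*_SC_*.txt")})
    for sid in subjects:
        sc = scio.read_connectome(
            sc_dir / scio.connectome_filename(sid, "SC", 1), parc, "SC", sid, 1
        )
        fcs = []
        j = 1
        while (fc_dir / scio.connectome_filename(sid, "FC", j)).exists():
            fcs.append(
                scio.read_connectome(
                    fc_dir / scio.connectome_filename(sid, "FC", j), parc, "FC",
                    sid, j,
                )
            )
            j += 1
        connectomes[sid] = (sc, fcs)
    run.log(f"loaded {len(connectomes)} subjects from {sc_dir} / {fc_dir}")
    return parc, pedigree, cohort, connectomes


def _couple_stage(run: _Run, parc, connectomes):
    cfg = run.cfg
    region_cols = [f"region_{k:03d}" for k in range(parc.n_regions)]
    mean_rows, per_meas_rows = [], []
    strength_sc_rows, strength_fc_rows = [], []
    variant_tables = {v: [] for v in cfg.variants}
    for sid, (sc, fcs) in connectomes.items():
        fc_mean = cp.average_fc(fcs)
        for variant in cfg.variants:
            cv = cp.compute_coupling(sc, fc_mean, parc, variant)
            variant_tables[variant].append(
                {"subject_id": sid, "measurement_index": 1,
                 **dict(zip(region_cols, cv.values))}
            )
        for j, fc in enumerate(fcs, start=1):
            cv = cp.regional_coupling(sc, fc)
            per_meas_rows.append(
                {"subject_id": sid, "measurement_index": j,
                 **dict(zip(region_cols, cv.values))}
            )
            strength_fc_rows.append(
                {"subject_id": sid, "measurement_index": j,
                 **dict(zip(region_cols, cp.node_strength(fc).values))}
            )
        strength_sc_rows.append(
            {"subject_id": sid, "measurement_index": 1,
             **dict(zip(region_cols, cp.node_strength(sc).values))}
        )
    tables = {
        "coupling_mean": PhenotypeTable(pd.DataFrame(variant_tables["whole_brain"])),
        "coupling_by_measurement": PhenotypeTable(pd.DataFrame(per_meas_rows)),
        "sc_strength": PhenotypeTable(pd.DataFrame(strength_sc_rows)),
        "fc_strength": PhenotypeTable(pd.DataFrame(strength_fc_rows)),
    }
    for name, tbl in tables.items():
        run.write_table(tbl, f"{name}.tsv")
    for variant in cfg.variants:
        if variant != "whole_brain":
            tbl = PhenotypeTable(pd.DataFrame(variant_tables[variant]))
            run.write_table(tbl, f"coupling_{variant}.tsv")
            tables[f"coupling_{variant}"] = tbl
    run.log(f"coupling computed for variants {list(cfg.variants)}")
    return tables


def _group_mean(table: PhenotypeTable, measurements) -> np.ndarray:
    t = table.table
    sub = t[t["measurement_index"].isin(measurements)]
    per_subject = sub.groupby("subject_id")[table.region_columns].mean()
    return per_subject.mean(axis=0).to_numpy()


def _reliability_stage(run: _Run, tables):
    per_meas = tables["coupling_by_measurement"]
    m = sorted(per_meas.table["measurement_index"].unique())
    if len(m) < 2:
        run.log("reliability skipped: fewer than 2 FC measurements")
        return
    half = len(m) // 2
    a = _group_mean(per_meas, m[:half])
    b = _group_mean(per_meas, m[half:])
    ba = bland_altman(a, b)
    r, p = agreement_correlation(a, b, n_perm=run.cfg.n_perm, seed=run.cfg.seed)
    run.summary["reliability"] = {
        "bias": ba.mean_difference,
        "sd_of_differences": ba.sd_of_differences,
        "loa_lower": ba.loa_lower,
        "loa_upper": ba.loa_upper,
        "pearson_r": r,
        "permutation_p": p,
        "n_regions": ba.n,
    }
    run.log(f"reliability: bias={ba.mean_difference:.4f} r={r:.3f}")


def _glm_stage(run: _Run, tables, cohort):
    design = build_design(cohort)
    results = fit_regional_glm(
        tables["coupling_mean"], design, alpha=run.cfg.alpha
    )
    scio.write_table(results, run.out / "glm.tsv", header=run.header)
    n_sig = int(results["significant"].sum())
    run.summary["glm"] = {
        "n_tests": int(len(results)),
        "n_significant": n_sig,
        "alpha": run.cfg.alpha,
    }
    run.log(f"glm: {n_sig} significant coefficients at FDR {run.cfg.alpha}")
    return results


def _heritability_stage(run: _Run, tables, cohort, pedigree):
    cfg = run.cfg
    phen = tables["coupling_by_measurement"]
    if cfg.subgroup_filter:
        keep = cohort.query(cfg.subgroup_filter)["subject_id"]
        pedigree = filter_pedigree(pedigree, keep)
        phen = PhenotypeTable(
            phen.table[phen.table["subject_id"].isin(set(keep))].reset_index(
                drop=True
            )
        )
        run.log(
            f"subgroup filter {cfg.subgroup_filter!r}: {pedigree.n_subjects} subjects"
        )
    h2 = regional_heritability(
        phen,
        cohort,
        pedigree,
        covariates=("age", "sex", "handedness"),
        extra_covariates={
            "sc_strength": tables["sc_strength"],
            "fc_strength": tables["fc_strength"],
        },
    )
    scio.write_table(h2, run.out / "h2.tsv", header=run.header)
    run.summary["heritability"] = {
        "n_regions_fit": int(len(h2)),
        "median_h2": float(h2["h2"].median()) if len(h2) else None,
        "n_subjects": pedigree.n_subjects,
    }
    run.log(f"heritability: median h2 = {run.summary['heritability']['median_h2']}")
    return h2


def _netstats_stage(run: _Run, parc, tables, h2):
    cfg = run.cfg
    out = {}
    maps = {"coupling": _group_mean(tables["coupling_mean"], [1])}
    if h2 is not None and len(h2) == parc.n_regions:
        maps["h2"] = h2["h2"].to_numpy()
    for name, values in maps.items():
        summary = network_summary(values, parc)
        contrast = permutation_p_t(
            values, parc, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha
        )
        out[name] = {
            "summary": summary.table.to_dict(orient="records"),
            "networks": contrast.networks,
            "t": np.where(np.isnan(contrast.t), None, contrast.t).tolist(),
            "p_one_sided": np.where(
                np.isnan(contrast.p_one_sided), None, contrast.p_one_sided
            ).tolist(),
        }
    with open(run.out / "netstats.json", "w") as fh:
        json.dump({"_provenance": run.header, **out}, fh, indent=2)
    run.summary["netstats"] = {"maps": list(maps)}
    run.log(f"netstats written for maps {list(maps)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    run = _Run(config)
    stage = "setup"
    try:
        if config.run_simulate and not config.parcellation:
            stage = "simulate"
            parc, pedigree, cohort, connectomes = _simulate_inputs(run)
        else:
            stage = "load"
            parc, pedigree, cohort, connectomes = _load_inputs(run)
        tables = None
        if config.run_couple:
            stage = "couple"
            tables = _couple_stage(run, parc, connectomes)
        if config.run_reliability and tables:
            stage = "reliability"
            _reliability_stage(run, tables)
        if config.run_glm and tables and cohort is not None:
            stage = "glm"
            _glm_stage(run, tables, cohort)
        h2 = None
        if config.run_heritability and tables and pedigree is not None:
            stage = "heritability"
            h2 = _heritability_stage(run, tables, cohort, pedigree)
        if config.run_netstats and tables:
            stage = "netstats"
            _netstats_stage(run, parc, tables, h2)
    except Exception as exc:
        run.log(f"FAILED at stage {stage}: {exc}")
        run.finish()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    run.finish()
    return run.out
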