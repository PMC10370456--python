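"""End-to-end experiment orchestration.

An experiment is described by a :class:`RunConfig` (serializable to YAML),
and produces a directory of plain-text artifacts: a data manifest, per-data
set tables, summary tables, and a provenance record.  Every run is fully
determined by the config (including its master seed); re-running a config
reproduces the outputs byte for byte.  Each output table carries the config
hash in a header comment.

Experiments
-----------
``simulate``  write the simulated collection (FASTA + Newick + manifest).
``tworun``    the two-seed reproducibility protocol over the collection.
``q3``        the two-run protocol plus the true-tree-seeded third run.
``forest``    optimality-forest construction per data set.
``report``    summary + pattern-verdict tables from prior outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evolve import (
    SimDataset,
    derive_seed,
    hundred_like_design,
    ladder_design,
    make_collection,
)
from .forest import breadth_vs_information, build_forest, forest_frame
from .reproducibility import (
    DEFAULT_SEEDS,
    LL_TIE_TOL,
    evaluate_patterns,
    records_frame,
    run_collection,
)
from .search import SearchConfig

__all__ = ["RunConfig", "run_experiment", "validate_against_patterns"]

EXPERIMENTS = ("simulate", "tworun", "q3", "forest", "report")


@dataclass
class RunConfig:
    """Full description of one experiment run."""

    experiment: str = "tworun"
    out_dir: str = "experiment"
    # collection design
    design: str = "hundred"           # "hundred" | "ladder"
    n_datasets: int = 100             # hundred-like designs
    n_taxa: int = 16
    n_levels: int = 3                 # ladder designs
    per_level: int = 15
    ladder_n_taxa: int = 16
    # engine
    n_starts: int = 3
    epsilon: float = 1e-4
    moves: tuple = ("nni",)
    refine_k: int = 3
    seeds: tuple = DEFAULT_SEEDS
    # forest
    forest_n_starts: int = 5
    screen_margin: float | None = 5.0
    # reproducibility of the whole run
    master_seed: int = 0
    resume: bool = False
    progress: bool = False

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"invalid field 'experiment': {self.experiment!r}; "
                f"choose from {EXPERIMENTS}"
            )
        if self.design not in ("hundred", "ladder"):
            raise ValueError(f"invalid field 'design': {self.design!r}")
        if tuple(self.seeds)[0] == tuple(self.seeds)[1]:
            raise ValueError("invalid field 'seeds': the two seeds must differ")

    # -- serialization ------------------------------------------------- #

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["moves"] = list(self.moves)
        d["seeds"] = list(self.seeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("moves", "seeds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (I/O and progress fields
        excluded), stamped into every output table header."""
        d = self.to_dict()
        for key in ("out_dir", "resume", "progress"):
            d.pop(key, None)
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- derived objects ----------------------------------------------- #

    def sim_design(self):
        if self.design == "hundred":
            return hundred_like_design(
                master_seed=self.master_seed, n_datasets=self.n_datasets,
                n_taxa=self.n_taxa,
            )
        return ladder_design(
            master_seed=self.master_seed, n_levels=self.n_levels,
            per_level=self.per_level, n_taxa=self.ladder_n_taxa,
        )

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            n_starts=self.n_starts, epsilon=self.epsilon,
            moves=tuple(self.moves), refine_k=self.refine_k,
        )


# ---------------------------------------------------------------------- #
# table I/O with config-hash headers


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} "
                 f"phylorepro={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------- #
# experiment steps


def _write_collection(datasets: list[SimDataset], out: Path,
                      cfg: RunConfig) -> None:
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in datasets:
        ds.alignment.to_fasta(data_dir / f"{ds.dataset_id}.fasta")
        (data_dir / f"{ds.dataset_id}.true.nwk").write_text(
            ds.true_tree.to_newick() + "\n")
        rows.append({
            "dataset_id": ds.dataset_id, "seed": ds.seed,
            "n_taxa": ds.alignment.n_taxa(), "length": ds.alignment.length,
            "tree_length": ds.true_tree.tree_length(),
            "information": ds.information, "level": ds.level,
            "model": ds.model.kind,
            "params": json.dumps(ds.params, sort_keys=True),
        })
    _write_table(pd.DataFrame(rows), out / "manifest.tsv", cfg)


def _provenance(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(json.dumps({
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "phylorepro_version": __version__,
        "numpy_version": np.__version__,
    }, indent=2, sort_keys=True))


def run_experiment(cfg: RunConfig) -> Path:
    """Run one experiment; returns the output directory.

    With ``cfg.resume`` data sets already present in the output tables are
    skipped; without it, an existing records table for the same experiment
    is refused to avoid silently mixing runs.
    """
    out = Path(cfg.out_dir)
    _provenance(cfg, out)
    datasets = make_collection(cfg.sim_design())

    if cfg.experiment == "simulate":
        _write_collection(datasets, out, cfg)
        return out

    if cfg.experiment in ("tworun", "q3"):
        records_path = out / cfg.experiment / "records.tsv"
        done: set[str] = set()
        if records_path.exists():
            if not cfg.resume:
                raise FileExistsError(
                    f"{records_path} exists; pass resume to continue or "
                    "choose a fresh out_dir"
                )
            done = set(read_table(records_path).dataset_id)
            datasets = [d for d in datasets if d.dataset_id not in done]
        records = run_collection(
            datasets, cfg_base=cfg.search_config(), seeds=tuple(cfg.seeds),
            with_q3=(cfg.experiment == "q3"), progress=cfg.progress,
        )
        df = records_frame(records)
        if done:
            df = pd.concat([read_table(records_path), df], ignore_index=True)
        _write_table(df, records_path, cfg)
        _write_summary(df, out / cfg.experiment, cfg)
        return out

    if cfg.experiment == "forest":
        recs = []
        for ds in datasets:
            rec = build_forest(
                ds.alignment, ds.model, ds.true_tree,
                n_starts=cfg.forest_n_starts,
                seed=derive_seed(ds.seed, 41),
                cfg=cfg.search_config(),
                screen_margin=cfg.screen_margin,
                dataset_id=ds.dataset_id,
            )
            rec.information = ds.information
            rec.level = ds.level
            if cfg.progress:
                print(f"{ds.dataset_id}: forest n={rec.n_distinct} "
                      f"breadth={rec.breadth}")
            recs.append(rec)
        _write_table(forest_frame(recs), out / "forest" / "forest.tsv", cfg)
        if cfg.design == "ladder":
            levels = breadth_vs_information(recs)
            lv = levels.copy()
            lv["spearman_rho"] = levels.attrs["spearman_rho"]
            lv["spearman_p"] = levels.attrs["spearman_p"]
            _write_table(lv, out / "forest" / "levels.tsv", cfg)
        return out

    # report
    report_dir = out / "report"
    for sub in ("tworun", "q3"):
        records_path = out / sub / "records.tsv"
        if records_path.exists():
            df = read_table(records_path)
            _write_summary(df, report_dir, cfg, prefix=f"{sub}_")
            verdict = validate_against_patterns(records_path)
            _write_table(verdict, report_dir / f"{sub}_patterns.tsv", cfg)
    if not any(report_dir.glob("*.tsv")):
        raise FileNotFoundError(
            f"no tworun/q3 records under {out}; run those experiments first"
        )
    return out


def _summary_frame(df: pd.DataFrame) -> pd.DataFrame:
    irr = df[~df.reproducible]
    rep = df[df.reproducible]
    rows = [{
        "n_datasets": len(df),
        "n_irreproducible": len(irr),
        "pct_irreproducible": 100.0 * len(irr) / len(df),
        "mean_d_q1q2_irr": irr.d_q1q2.mean() if len(irr) else None,
        "mean_d_q1t_irr": irr.d_q1t.mean() if len(irr) else None,
        "mean_d_q2t_irr": irr.d_q2t.mean() if len(irr) else None,
        "mean_d_q1t_rep": rep.d_q1t.mean() if len(rep) else None,
        "mean_abs_dll_12": df.dll_12.abs().mean(),
        "mean_abs_dll_1t": df.dll_1t.abs().mean(),
        "frac_ll1_ge_true": float((df.ll1 >= df.ll_true - LL_TIE_TOL).mean()),
    }]
    return pd.DataFrame(rows)


def _write_summary(df: pd.DataFrame, dirpath: Path, cfg: RunConfig,
                   prefix: str = "") -> None:
    _write_table(_summary_frame(df), dirpath / f"{prefix}summary.tsv", cfg)


def validate_against_patterns(records_path, seed: int = 0) -> pd.DataFrame:
    """Evaluate the structural patterns P1-P4 on a records table.

    Returns a human-readable verdict table with one row per registered
    pattern; patterns whose preconditions are unmet (e.g. no irreproducible
    data sets) are reported "not applicable" rather than failed.
    """
    df = read_table(records_path)
    from .reproducibility import ReproRecord  # for the record-based API

    # rebuild the minimal per-row structure evaluate_patterns needs
    class _Row:
        pass

    records = []
    for _, r in df.iterrows():
        rec = ReproRecord(
            dataset_id=r.dataset_id, q1=None, q2=None,
            ll1=r.ll1, ll2=r.ll2, ll_true=r.ll_true,
            d_q1q2=r.d_q1q2, d_q1t=r.d_q1t, d_q2t=r.d_q2t,
            dll_12=r.dll_12, dll_1t=r.dll_1t, dll_2t=r.dll_2t,
            reproducible=bool(r.reproducible),
            level=None if pd.isna(r.level) else int(r.level),
        )
        records.append(rec)
    patterns = evaluate_patterns(records, seed=seed)
    rows = []
    descriptions = {
        "P1": "irreproducible runs differ less from each other than from truth",
        "P2": "the two runs are equally inaccurate (overlapping 95% CIs)",
        "P3": "inferred LL >= optimized true-tree LL in >=90% of data sets",
        "P4": "irreproducibility fraction non-increasing with information",
    }
    for name in ("P1", "P2", "P3", "P4"):
        p = patterns[name]
        if not p["applicable"]:
            verdict = "not applicable"
        else:
            verdict = "pass" if p["pass"] else "FAIL"
        detail = {k: v for k, v in p.items() if k not in ("applicable", "pass")}
        rows.append({
            "pattern": name,
            "description": descriptions[name],
            "verdict": verdict,
            "detail": json.dumps(detail, default=str, sort_keys=True),
        })
    return pd.DataFrame(rows)
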