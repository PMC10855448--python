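"""End-to-end pipeline: stability → consensus → impact → overview → report.

A run is fully determined by its :class:`RunConfig` plus the input table (or
the simulation seed when no input is given); re-running with the same config
produces byte-identical JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import consensus as _consensus
from . import impact as _impact
from . import overview as _overview
from .datasets import CONDITIONS
from .qpcr_data import CtMatrix, RefstabError, read_ct_table, slice_groups
from .stability import run_all_methods
from .synthetic_data import msc_study_fixture

logger = logging.getLogger("refstab")


@dataclasses.dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    input: str | None = None           # Ct table path; None -> simulated fixture
    hkgs: Sequence[str] | None = None  # None -> genes tagged candidate_hkg
    targets: Sequence[str] | None = None
    conditions: dict[str, Sequence[str]] | None = None  # name -> group filter
    seed: int = 0
    outdir: str = "refstab_out"
    output_format: str = "csv"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = (
            {k: list(v) for k, v in self.conditions.items()}
            if self.conditions
            else None
        )
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise RefstabError(f"config {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise RefstabError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)


def _load(cfg: RunConfig) -> CtMatrix:
    if cfg.input is None:
        logger.info("no input table; simulating study-calibrated fixture (seed=%d)", cfg.seed)
        return msc_study_fixture(cfg.seed)
    return read_ct_table(cfg.input)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[str] = []

    stage = "load"
    try:
        m = _load(cfg)
        hkgs = list(cfg.hkgs) if cfg.hkgs else m.hkgs
        targets = list(cfg.targets) if cfg.targets else m.targets
        unknown = [g for g in [*hkgs, *targets] if g not in m.genes]
        if unknown:
            raise RefstabError(f"unknown gene(s) in config: {unknown}")
        conditions = (
            {k: list(v) for k, v in cfg.conditions.items()}
            if cfg.conditions
            else {k: list(v) for k, v in CONDITIONS.items() if set(v) <= set(m.groups)}
        )

        # -- stability + consensus per condition --------------------------
        stage = "stability/consensus"
        rankings: dict[str, _consensus.ConsensusRanking] = {}
        for name, groups in conditions.items():
            d = slice_groups(m, groups)
            tables = run_all_methods(d, hkgs)
            cons = _consensus.rank_and_aggregate(tables, condition=name)
            rankings[name] = cons
            safe = name.replace("/", "-")
            pd.concat([t.to_frame() for t in tables]).to_csv(
                out / f"stability_{safe}.csv"
            )
            cons.to_frame().to_csv(out / f"consensus_{safe}.csv")
            for t in tables:
                for rec in t.extras.get("tie_log", []):
                    log.append(f"{name}: {rec}")
        logger.info("stability/consensus done for %d conditions", len(conditions))

        # -- impact analysis ----------------------------------------------
        stage = "impact"
        impact_summary = {}
        if targets:
            pooled_name = max(conditions, key=lambda k: len(conditions[k]))
            pooled = slice_groups(m, conditions[pooled_name])
            cons = rankings[pooled_name]
            best, worst = cons.best, cons.worst
            e_best = _impact.relative_expression(pooled, targets, best)
            e_worst = _impact.relative_expression(pooled, targets, worst)
            for target in targets:
                rm_best = _impact.ratio_matrix(e_best, target)
                rm_worst = _impact.ratio_matrix(e_worst, target)
                art = _impact.artifact_matrix(rm_best, rm_worst)
                safe = target.replace("/", "-")
                rm_best.ratios.to_csv(out / f"ratios_{safe}_best.csv")
                rm_worst.ratios.to_csv(out / f"ratios_{safe}_worst.csv")
                art.modulation.to_csv(out / f"artifact_{safe}.csv")
                entry = {
                    "best_hkg": best,
                    "worst_hkg": worst,
                    "ratio_flags_best": rm_best.flag_count(),
                    "ratio_flags_worst": rm_worst.flag_count(),
                    "artifact_flags": art.flag_count(),
                }
                if len(pooled.groups) >= 2:
                    gc_b = _impact.compare_groups(e_best, target)
                    gc_w = _impact.compare_groups(e_worst, target)
                    entry["group_test"] = gc_b.test
                    entry["significant_pairs_best"] = [
                        list(p) for p in gc_b.significant_pairs
                    ]
                    entry["significant_pairs_worst"] = [
                        list(p) for p in gc_w.significant_pairs
                    ]
                impact_summary[target] = entry

        # -- expression overview ------------------------------------------
        stage = "overview"
        group_means = m.values.groupby(m.meta["group"], sort=False).mean()
        pca = _overview.pca_overview(group_means[hkgs])
        tree = _overview.hier_cluster(group_means[hkgs])
        overview_payload = {
            "level": "group-means",
            "variance_pct": [float(v) for v in pca.variance_pct_rounded],
            "leaf_order": tree.leaf_order,
            "first_merge": sorted(tree.first_merge()),
        }
        (out / "overview.json").write_text(
            json.dumps(overview_payload, indent=1, sort_keys=True)
        )

        # -- summary --------------------------------------------------------
        stage = "summary"
        summary = {
            "config": cfg.to_dict(),
            "n_samples": len(m.samples),
            "genes": m.genes,
            "hkgs": hkgs,
            "targets": targets,
            "conditions": {
                name: {
                    "best_hkg": rankings[name].best,
                    "worst_hkg": rankings[name].worst,
                    "geomean": {
                        g: float(v)
                        for g, v in rankings[name].geomean_rounded.items()
                    },
                }
                for name in conditions
            },
            "impact": impact_summary,
            "overview": overview_payload,
            "log": log,
            "elapsed_s": None,  # filled below, excluded from determinism
        }
        elapsed = round(time.time() - t0, 3)
        summary_det = {k: v for k, v in summary.items() if k != "elapsed_s"}
        (out / "summary.json").write_text(
            json.dumps(summary_det, indent=1, sort_keys=True)
        )
        summary["elapsed_s"] = elapsed
        logger.info("pipeline finished in %.2fs", elapsed)
        return summary
    except RefstabError:
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        raise RefstabError(f"pipeline failed in stage {stage!r}: {exc}") from exc
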