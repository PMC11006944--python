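"""End-to-end pipeline: simulate (or ingest) -> estimate -> mode tree -> analyze."""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from . import __version__
from .estimator import estimate_by_epoch, mode_context_tree
from .io import RunConfig, read_session, write_session, write_tree
from .simulate import CohortConfig, generate_cohort
from .stats import run_misprediction_analysis
from .trees import context_from_string

logger = logging.getLogger(__name__)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the canonicalized config; changes iff a parameter does."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict


def run_pipeline(config: RunConfig, out_dir: Union[str, Path]) -> PipelineResult:
    """Run the full analysis and write an artifact bundle under ``out_dir``.

    The bundle contains the session CSVs, one tree JSON per participant and
    epoch, one mode tree per epoch, the misprediction report TSVs and a
    manifest recording config, hash and versions.  The run is a deterministic
    function of the config; on any stage failure partial outputs are removed.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out_dir)
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run(config: RunConfig, out_dir: Path) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # stage 1: sessions
    if config.cohort_dir is not None:
        cohort_dir = Path(config.cohort_dir)
        if not cohort_dir.is_dir():
            raise FileNotFoundError(f"[simulate] cohort directory not found: {cohort_dir}")
        cohort = [read_session(p) for p in sorted(cohort_dir.glob("*.csv"))]
        if not cohort:
            raise FileNotFoundError(f"[simulate] no session CSVs in {cohort_dir}")
    else:
        cc = CohortConfig(
            n_participants=config.n_participants,
            n_trials=config.n_trials,
            epoch_boundaries=config.epoch_boundaries,
            seed=config.seed,
        )
        cohort = generate_cohort(cc)
    session_dir = out_dir / "sessions"
    session_dir.mkdir(exist_ok=True)
    session_files = [
        write_session(s, session_dir / f"{s.participant_id}.csv").name for s in cohort
    ]

    # stage 2: per-participant, per-epoch tree estimation
    tree_dir = out_dir / "trees"
    tree_dir.mkdir(exist_ok=True)
    epoch_trees: dict[int, list] = {}
    tree_files = []
    for s in cohort:
        results = estimate_by_epoch(
            s, config.epoch_boundaries, K=config.K, alpha=config.alpha, min_count=config.min_count
        )
        for e, res in results.items():
            epoch_trees.setdefault(e, []).append(res.tree)
            f = write_tree(res.tree, tree_dir / f"{s.participant_id}_epoch{e}.json",
                           extra={"metadata": res.to_dict() | {"participant": s.participant_id, "epoch": e}})
            tree_files.append(f.name)
        logger.info("estimated %d epoch tree(s) for %s", len(results), s.participant_id)

    # stage 3: mode tree per epoch
    mode_dir = out_dir / "mode_trees"
    mode_dir.mkdir(exist_ok=True)
    mode_files = []
    for e, trees in sorted(epoch_trees.items()):
        mode = mode_context_tree(trees, config.mode_threshold)
        f = write_tree(
            mode.tree,
            mode_dir / f"mode_epoch{e}.json",
            extra={"counts": mode.counts_by_string(), "n_trees": mode.n_trees,
                   "threshold": mode.threshold},
        )
        mode_files.append(f.name)

    # stage 4: misprediction analysis
    contexts = [context_from_string(s) for s in config.contexts]
    report, participant_means = run_misprediction_analysis(
        cohort, contexts, trim=config.trim, q=config.q
    )
    report_path = out_dir / "misprediction_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    means_path = out_dir / "participant_means.tsv"
    participant_means.to_csv(means_path, sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "version": __version__,
        "sessions": session_files,
        "trees": sorted(tree_files),
        "mode_trees": mode_files,
        "reports": [report_path.name, means_path.name],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(out_dir, manifest)
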