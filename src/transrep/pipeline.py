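"""End-to-end orchestration: curate -> power -> replicability -> bias ->
concordance -> (optional) LD scan, with deterministic TSV outputs.

Every output table carries a header comment with the tool version and a
hash of the run configuration, so identical configurations yield
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effect_concordance import concordance_stats, windowed_replicability_profile
from .ld_divergence import read_vcf, sliding_window_scan
from .power_calc import expected_replications
from .replicability_stats import publication_bias_bounds, summarize_replicability
from .replication_db import load_tables, select_attempts, write_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    studies_path: str
    associations_path: str
    attempts_path: str
    out_dir: str
    alpha: float = 0.05
    null_convention: str = "any_direction"
    select_mode: str = "all"
    n_unreported_max: int = 0
    profile_axis: str = "OR"
    profile_width: float = 0.3
    profile_step: float = 0.05
    vcf_path: str | None = None
    pops_path: str | None = None
    focal_snp: str | None = None
    window: int = 50
    step: int = 5
    span: int = 300
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("studies_path", "associations_path", "attempts_path"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: no such file: {path}")
        if self.vcf_path is not None:
            for name in ("vcf_path", "pops_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name}: no such file: {path}")

    def hash(self) -> str:
        # the output location does not influence what is computed
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _comment(config: RunConfig) -> str:
    return f"transrep {__version__} config={config.hash()} seed={config.seed}"


def run_full_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a manifest of outputs and key numbers."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comment = _comment(config)
    manifest: dict = {"version": __version__, "config": asdict(config),
                      "config_hash": config.hash(), "outputs": {}}

    def stage(name):
        logger.info("stage %s", name)
        return _StageTimer(name)

    with stage("curate") as _:
        try:
            tables = load_tables(config.studies_path, config.associations_path,
                                 config.attempts_path)
            from .replication_db import apply_discovery_filters
            kept, exclusions = apply_discovery_filters(tables.associations,
                                                       tables.studies)
            write_table(kept, out_dir / "associations_curated.tsv", comment)
            write_table(exclusions, out_dir / "exclusions.tsv", comment)
        except Exception as exc:  # noqa: BLE001
            raise StageError("curate", exc) from exc

    with stage("power"):
        try:
            attempts = tables.attempts.merge(
                kept[["snp_id", "or_discovery", "log_or", "region_id"]],
                on="snp_id", how="inner",
            )
            expected, attempts = expected_replications(attempts,
                                                       alpha=config.alpha)
            attempts = select_attempts(attempts, config.select_mode,
                                       associations=kept)
            if config.select_mode != "all":
                expected = float(attempts["power"].sum())
            write_table(attempts, out_dir / "attempts_powered.tsv", comment)
        except Exception as exc:  # noqa: BLE001
            raise StageError("power", exc) from exc

    with stage("replicability"):
        try:
            summary = summarize_replicability(attempts, alpha=config.alpha,
                                              convention=config.null_convention)
            summary_frame = pd.DataFrame([summary.__dict__])
            write_table(summary_frame, out_dir / "summary.tsv", comment)
            manifest["replicability"] = summary.__dict__
        except Exception as exc:  # noqa: BLE001
            raise StageError("replicability", exc) from exc

    with stage("bias"):
        try:
            bound = publication_bias_bounds(
                observed=summary.n_success, alpha=config.alpha,
                p_same_dir=0.5, n_gathered=summary.n_attempts,
                n_unreported_max=config.n_unreported_max,
            )
            write_table(pd.DataFrame([bound.__dict__]),
                        out_dir / "bias_bounds.tsv", comment)
            manifest["bias"] = bound.__dict__
        except Exception as exc:  # noqa: BLE001
            raise StageError("bias", exc) from exc

    with stage("concordance"):
        try:
            pairs = attempts.assign(
                log_or_discovery=attempts["log_or"].astype(float),
                log_or_replication=np.log(
                    attempts["or_replication"].astype(float)),
            )
            stats_all = concordance_stats(pairs)
            write_table(pd.DataFrame([stats_all.__dict__]),
                        out_dir / "concordance.tsv", comment)
            profile = windowed_replicability_profile(
                attempts, axis=config.profile_axis,
                width=config.profile_width, step=config.profile_step,
                alpha=config.alpha,
            )
            write_table(profile, out_dir / "profile.tsv", comment)
            manifest["concordance"] = stats_all.__dict__
        except Exception as exc:  # noqa: BLE001
            raise StageError("concordance", exc) from exc

    if config.vcf_path is not None:
        with stage("varld-scan"):
            try:
                panels = read_vcf(config.vcf_path, config.pops_path)
                if len(panels) != 2:
                    raise ValueError("expected exactly two populations")
                panel1, panel2 = panels.values()
                focal = config.focal_snp
                if focal is None:
                    focal = panel1.n_snps // 2
                windows = sliding_window_scan(
                    panel1, panel2, focal, window=config.window,
                    step=config.step, span=config.span,
                )
                write_table(windows, out_dir / "windows.tsv", comment)
                manifest["outputs"]["windows"] = str(out_dir / "windows.tsv")
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("varld-scan", exc) from exc

    manifest["outputs"].update({
        name: str(out_dir / f"{name}.tsv")
        for name in ("summary", "bias_bounds", "concordance", "profile")
    })
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
    return manifest


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.start = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.start
        logger.info("stage %s finished in %.2fs", self.name, elapsed)
        return False
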