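"""End-to-end orchestration: images → histograms → zones → observation table
→ beta-regression fits → efficacy report.

Every stage reads and writes plain documented formats (PNG images, CSV
tables, S1-style XLSX histograms, JSON reports), so each can also be run
standalone. A manifest with SHA-256 checksums is written per run; reruns
with the same config and seed reproduce identical observation tables and
posterior summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import betareg, efficacy, quantify, segment, synthetic

__all__ = ["RunConfig", "run_pipeline", "import_s1_histograms", "PipelineError"]

log = logging.getLogger("weedcover")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run. Exactly one input mode is active."""

    mode: str = "simulate"  # images | histograms | observations | simulate
    out_dir: str = "results/run"
    seed: int = 0
    # simulate mode
    truth: dict[str, float] | None = None
    design: dict[str, Any] | None = None
    image_size: tuple[int, int] = (160, 160)
    simulate_images: bool = True
    # images mode
    images_dir: str | None = None
    sidecar: str | None = None  # CSV: filename,group,pot_id,day
    # histograms / observations modes
    histograms_path: str | None = None
    observations_path: str | None = None
    # quantification
    levels_per_channel: int = 256
    top_k: int | str = 6
    require_shared: bool = True
    # segmentation
    gray_threshold: float = 0.85
    brightness_range: tuple[float, float] = (60.0, 220.0)
    smoothing_radius: int = 3
    # model / sampler
    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000
    prior_mean_scale: float = 2.5
    prior_precision_scale: float = 1.0
    # estimands
    estimand_days: tuple[float, ...] = (5.0,)
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("images", "histograms", "observations", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _truth_design(cfg: RunConfig) -> tuple[synthetic.TruthParams, synthetic.StudyDesign]:
    truth = (
        synthetic.TruthParams(**cfg.truth) if cfg.truth else synthetic.default_truth()
    )
    if cfg.design:
        d = dict(cfg.design)
        if "days" in d:
            d["days"] = tuple(float(x) for x in d["days"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        design = synthetic.StudyDesign(**d)
    else:
        design = synthetic.StudyDesign()
    return truth, design


# ---------------------------------------------------------------------------
# input stages


def _stage_simulate(cfg: RunConfig, out: Path) -> pd.DataFrame:
    truth, design = _truth_design(cfg)
    obs = synthetic.simulate_proportions(truth, design, cfg.seed)
    log.info("simulated %d observations (%d pots/group, days %s)",
             len(obs), design.pots_per_group, list(design.days))
    return obs


def _read_sidecar(cfg: RunConfig) -> pd.DataFrame:
    if cfg.sidecar is None:
        raise PipelineError("images mode requires a sidecar CSV (filename,group,pot_id,day)")
    side = pd.read_csv(cfg.sidecar)
    need = {"filename", "group", "pot_id", "day"}
    if not need <= set(side.columns):
        raise PipelineError(f"sidecar must have columns {sorted(need)}")
    return side


def _stage_images(cfg: RunConfig, out: Path, manifest: list[Path]) -> pd.DataFrame:
    """Quantify green cover per image; treated images ("T") are segmented and
    contribute one P0 and one P1 record each."""
    side = _read_sidecar(cfg)
    base = Path(cfg.images_dir or ".")
    entries: list[tuple[str, str, float, quantify.PixelHistogram]] = []
    for row in side.itertuples():
        path = base / str(row.filename)
        try:
            img = quantify.load_image(path)
        except Exception as exc:
            raise PipelineError(f"quantify stage: cannot read {path}: {exc}") from exc
        group = str(row.group)
        if group == "T":
            try:
                mask = segment.segment_zones(
                    img,
                    gray_threshold=cfg.gray_threshold,
                    brightness_range=cfg.brightness_range,
                    smoothing_radius=cfg.smoothing_radius,
                )
            except Exception as exc:
                raise PipelineError(f"segment stage: {path}: {exc}") from exc
            for zone, glabel in ((segment.GRAY_ZONE, "P1"), (segment.NONGRAY_ZONE, "P0")):
                zimg = segment.apply_mask(img, mask, zone)
                label = f"{row.pot_id}_{glabel}_d{row.day}"
                hist = quantify.quantize_colors(zimg, cfg.levels_per_channel, label=label)
                entries.append((str(row.pot_id), glabel, float(row.day), hist))
        elif group in ("C", "P0", "P1"):
            label = f"{row.pot_id}_{group}_d{row.day}"
            hist = quantify.quantize_colors(img, cfg.levels_per_channel, label=label)
            entries.append((str(row.pot_id), group, float(row.day), hist))
        else:
            raise PipelineError(f"quantify stage: unknown group {group!r} for {path}")

    by_group: dict[str, list[quantify.PixelHistogram]] = {}
    for _, g, _, h in entries:
        by_group.setdefault(g, []).append(h)
    sel = quantify.GreenSelection(
        top_k=cfg.top_k, require_shared_across_groups=cfg.require_shared
    )
    codes = quantify.select_green_codes(by_group, sel)
    log.info("selected %d green codes: %s", len(codes),
             sorted(quantify.format_code(c) for c in codes))

    hist_path = out / "histograms.csv"
    quantify.write_histograms_csv([h for *_, h in entries], hist_path)
    manifest.append(hist_path)
    codes_path = out / "green_codes.json"
    codes_path.write_text(
        json.dumps(sorted(quantify.format_code(c) for c in codes), indent=2)
    )
    manifest.append(codes_path)

    return pd.DataFrame(
        [
            (f"{g}_{pot}", g, d, quantify.green_proportion(h, codes))
            for pot, g, d, h in entries
        ],
        columns=["pot_id", "group", "day", "proportion"],
    )


def _stage_histograms(cfg: RunConfig, out: Path) -> pd.DataFrame:
    """Observation table from labelled histograms; labels must parse as
    pot_GROUP_d<day> (the layout this package writes)."""
    path = Path(cfg.histograms_path or "")
    if path.suffix.lower() in (".xlsx", ".xls"):
        hists = import_s1_histograms(path)
    else:
        hists = quantify.read_histograms_csv(path)
    by_group: dict[str, list[quantify.PixelHistogram]] = {}
    parsed = []
    for h in hists:
        try:
            pot, group, dpart = (h.label or "").rsplit("_", 2)
            day = float(dpart.lstrip("d"))
        except Exception as exc:
            raise PipelineError(
                f"histograms stage: label {h.label!r} does not parse as pot_GROUP_d<day>"
            ) from exc
        parsed.append((pot, group, day, h))
        by_group.setdefault(group, []).append(h)
    sel = quantify.GreenSelection(
        top_k=cfg.top_k, require_shared_across_groups=cfg.require_shared
    )
    codes = quantify.select_green_codes(by_group, sel)
    log.info("selected green codes: %s", sorted(quantify.format_code(c) for c in codes))
    return pd.DataFrame(
        [
            (f"{g}_{pot}", g, d, quantify.green_proportion(h, codes))
            for pot, g, d, h in parsed
        ],
        columns=["pot_id", "group", "day", "proportion"],
    )


# ---------------------------------------------------------------------------
# model + efficacy stages


def _stage_fit(cfg: RunConfig, obs: pd.DataFrame, out: Path, manifest: list[Path]):
    y = obs["proportion"].to_numpy(float)
    if np.any((y <= 0) | (y >= 1)):
        obs = obs.assign(proportion=betareg.nudge_boundary(y))
        log.info("nudged %d boundary outcomes into (0,1)", int(np.sum((y <= 0) | (y >= 1))))

    ml, report = betareg.fit_ml(obs)
    log.info("ML fit: loglik=%.3f |grad|=%.2e", report.loglik, report.grad_norm)

    priors = betareg.PriorSpec(
        mean_scale=cfg.prior_mean_scale, precision_scale=cfg.prior_precision_scale
    )
    draws = betareg.sample_posterior(
        obs,
        priors=priors,
        n_chains=cfg.n_chains,
        n_iter=cfg.n_iter,
        n_warmup=cfg.n_warmup,
        seed=cfg.seed,
    )
    log.info("posterior: %d draws, accept=%.2f, max Rhat=%.3f",
             draws.n_draws, draws.accept_rate, max(draws.rhat.values()))

    draws_path = out / "draws.csv"
    draws.to_frame().to_csv(draws_path, index=False)
    manifest.append(draws_path)
    conv_path = out / "convergence.json"
    conv_path.write_text(
        json.dumps(
            {
                "rhat": draws.rhat,
                "ess": draws.ess,
                "accept_rate": draws.accept_rate,
                "n_chains": draws.n_chains,
                "n_warmup": draws.n_warmup,
                "seed": draws.seed,
                "warnings": draws.warnings_,
                "ml": {
                    "loglik": report.loglik,
                    "grad_norm": report.grad_norm,
                    "converged": report.converged,
                    "estimates": {k: v for k, v in zip(betareg.ALL_COEF, ml.as_array())},
                    "std_errors": report.std_errors,
                },
            },
            indent=2,
            default=float,
        )
    )
    manifest.append(conv_path)
    return ml, draws, obs


def _stage_efficacy(cfg: RunConfig, draws, out: Path, manifest: list[Path]) -> pd.DataFrame:
    groups = [g for g in ("P1", "P0", "T") if g in draws.groups]
    if not groups or "C" not in draws.groups:
        raise PipelineError(
            "efficacy stage needs the control group plus at least one treated group"
        )
    rows = []
    for day in cfg.estimand_days:
        for g in groups:
            ratios, flagged = efficacy.efficacy_ratio_draws(draws, day, g, "C")
            s = efficacy.summarize(
                ratios, ci_level=cfg.ci_level,
                estimand=f"theta_{g}({day:g})/theta_C({day:g})",
            )
            rows.append(
                (s.estimand, day, s.posterior_mean, s.ci_low, s.ci_high,
                 s.ci_level, s.n_draws, flagged)
            )
            log.info("%s: mean=%.3f CI=(%.3f, %.3f)", s.estimand,
                     s.posterior_mean, s.ci_low, s.ci_high)
    table = pd.DataFrame(
        rows,
        columns=["estimand", "day", "posterior_mean", "ci_low", "ci_high",
                 "ci_level", "n_draws", "flagged_draws"],
    )
    path = out / "efficacy.csv"
    table.to_csv(path, index=False)
    manifest.append(path)
    return table


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages and return {artifact name: path or table}.

    Writes observations.csv, draws.csv, convergence.json, efficacy.csv,
    run.log and manifest.json under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config: %s", json.dumps(dataclasses.asdict(config), default=str))
        if config.mode == "simulate":
            obs = _stage_simulate(config, out)
        elif config.mode == "images":
            obs = _stage_images(config, out, manifest)
        elif config.mode == "histograms":
            obs = _stage_histograms(config, out)
        else:
            obs = pd.read_csv(config.observations_path)
        betareg.validate_observations(
            obs.assign(
                proportion=np.clip(obs["proportion"], 1e-12, 1 - 1e-12)
            )
        )
        obs_path = out / "observations.csv"
        obs.to_csv(obs_path, index=False)
        manifest.append(obs_path)

        ml, draws, obs_fit = _stage_fit(config, obs, out, manifest)
        table = _stage_efficacy(config, draws, out, manifest)

        man_path = out / "manifest.json"
        man_path.write_text(
            json.dumps(
                {str(p.relative_to(out)): _sha256(p) for p in manifest}, indent=2
            )
        )
        return {
            "observations": obs_path,
            "draws": out / "draws.csv",
            "efficacy": table,
            "manifest": man_path,
            "ml_params": ml,
            "posterior": draws,
        }
    finally:
        log.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# supplementary-workbook import


def import_s1_histograms(path: str | Path) -> list[quantify.PixelHistogram]:
    """Read an S1-style workbook (one sheet per flowerpot image; columns for
    R, G, B and a pixel count, a Color/code column optional) into labelled
    histograms. Tolerates extra columns and header case; fails loudly naming
    the offending sheet otherwise."""
    xl = pd.ExcelFile(path, engine="openpyxl")
    out = []
    for sheet in xl.sheet_names:
        df = xl.parse(sheet)
        cols = {str(c).strip().lower(): c for c in df.columns}
        needed = {"r", "g", "b"}
        count_col = next(
            (cols[k] for k in ("pixels", "count", "pixel", "n") if k in cols), None
        )
        if not needed <= set(cols) or count_col is None:
            raise PipelineError(
                f"S1 import: sheet {sheet!r} lacks R/G/B/pixel-count columns "
                f"(found {list(df.columns)})"
            )
        counts: dict[tuple[int, int, int], int] = {}
        for i, row in df.iterrows():
            try:
                code = (int(row[cols["r"]]), int(row[cols["g"]]), int(row[cols["b"]]))
                n = int(row[count_col])
            except (TypeError, ValueError) as exc:
                raise PipelineError(f"S1 import: sheet {sheet!r} row {i}: {exc}") from exc
            if n < 0:
                raise PipelineError(f"S1 import: sheet {sheet!r} row {i}: negative count")
            counts[code] = counts.get(code, 0) + n
        total = sum(counts.values())
        if total <= 0:
            raise PipelineError(f"S1 import: sheet {sheet!r} has zero pixels")
        out.append(
            quantify.PixelHistogram(counts=counts, total_pixels=total, label=sheet)
        )
    return out


def save_images(series: list[synthetic.PotImage], out_dir: str | Path) -> pd.DataFrame:
    """Write a simulated image series as PNGs plus the sidecar CSV the images
    mode consumes. Returns the sidecar table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pi in series:
        group = "C" if pi.kind == "control" else "T"
        name = f"{pi.pot_id}_d{pi.day:g}.png"
        Image.fromarray(pi.image, mode="RGBA").save(out / name)
        rows.append((name, group, pi.pot_id, pi.day))
    side = pd.DataFrame(rows, columns=["filename", "group", "pot_id", "day"])
    side.to_csv(out / "sidecar.csv", index=False)
    return side
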