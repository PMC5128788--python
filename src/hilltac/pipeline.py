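"""End-to-end orchestration: table in, report bundle out.

A run loads (or simulates) a community table, then produces:

* ``diversity.csv`` — per-sample and pooled summary (N, S_obs, Hill numbers,
  Chao1, Good's coverage, F1, F2);
* ``tac_a<order>.csv`` per Hill order — smoothed taxa-accumulation curve
  (step, mean, sd);
* ``depth_analysis.csv`` — replicate Hill values over the subsampling depth
  grid (long format), plus ``stability.json`` with the first stable depth
  per order;
* ``rad_fits.csv`` and ``rad.json`` — log-normal and Zipf fits of the pooled
  abundances, the AIC-selected model, and the bootstrap deviation test
  against the log-normal;
* ``manifest.json`` — the effective configuration, seeds, package version,
  input checksum and a checksum for every output file.

Outputs are deterministic: re-running an identical configuration rewrites
byte-identical payloads (the manifest carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .accumulation import (
    DEFAULT_N_PERM,
    DEFAULT_REPS,
    DEFAULT_TOL,
    DEFAULT_WINDOW_FRAC,
    depth_analysis,
    smoothed_tac,
)
from .diversity_core import diversity_summary
from .io_tables import CommunityTable, pool_samples, read_shared, read_tsv
from .rad_models import DEFAULT_N_BOOT, deviation_test, fit_lognormal, fit_zipf, select_model
from .synthetic_data import CommunitySpec, amazon_like, make_study, texas_like

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_PRESETS = {"amazon": amazon_like, "texas": texas_like}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Exactly one input source must be set: ``input_path`` (``.shared`` or
    TSV), ``preset`` (``amazon``/``texas``), or a simulation spec via
    ``sim_tad``/``sim_s``/``sim_n_samples``/``sim_depth``.  Defaults mirror
    the owning modules' defaults.
    """

    input_path: str | None = None
    orientation: str = "taxa_by_samples"
    preset: str | None = None
    sim_tad: str | None = None
    sim_s: int = 5000
    sim_mu: float = 0.0
    sim_sigma: float = 2.0
    sim_gamma: float = 1.1
    sim_n_samples: int = 20
    sim_depth: int = 5000
    sim_overdispersion: float = 0.0
    orders: tuple[float, ...] = (0.0, 1.0, 2.0)
    n_perm: int = DEFAULT_N_PERM
    reps: int = DEFAULT_REPS
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0
    depths: tuple[int, ...] | None = None
    window_frac: float = DEFAULT_WINDOW_FRAC
    tol: float = DEFAULT_TOL
    out_dir: str = "hilltac_out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (# starts a comment)."""
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, "r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _parse_value(key, raw)
        return cls(**values)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Rebuild a config from a manifest's embedded ``config`` mapping."""
        d = dict(d)
        d["orders"] = tuple(d.get("orders", (0.0, 1.0, 2.0)))
        if d.get("depths") is not None:
            d["depths"] = tuple(d["depths"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orders"] = list(self.orders)
        d["depths"] = list(self.depths) if self.depths is not None else None
        return d


def _parse_value(key: str, raw: str):
    if raw.lower() in ("none", ""):
        return None
    if key in ("orders",):
        return tuple(float(x) for x in raw.split(","))
    if key in ("depths",):
        return tuple(int(x) for x in raw.split(","))
    if key in ("sim_s", "sim_n_samples", "sim_depth", "n_perm", "reps",
               "n_boot", "seed"):
        return int(raw)
    if key in ("sim_mu", "sim_sigma", "sim_gamma", "sim_overdispersion",
               "window_frac", "tol"):
        return float(raw)
    return raw


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_table(config: RunConfig) -> tuple[CommunityTable, str | None]:
    sources = [config.input_path is not None, config.preset is not None,
               config.sim_tad is not None]
    if sum(sources) != 1:
        raise ValueError(
            "exactly one of input_path, preset or sim_tad must be set"
        )
    if config.input_path is not None:
        path = Path(config.input_path)
        if path.suffix == ".shared":
            table = read_shared(path)
        else:
            table = read_tsv(path, orientation=config.orientation)
        return table, _sha256(path)
    if config.preset is not None:
        if config.preset not in _PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}")
        return _PRESETS[config.preset](seed=config.seed), None
    spec = CommunitySpec(
        S=config.sim_s, tad=config.sim_tad, mu=config.sim_mu,
        sigma=config.sim_sigma, gamma=config.sim_gamma, seed=config.seed,
    )
    table = make_study(
        spec, config.sim_n_samples, config.sim_depth,
        overdispersion=config.sim_overdispersion, seed=config.seed + 1,
    )
    return table, None


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Any stage failure raises :class:`PipelineError` naming the stage; files
    written before the failure are listed in a partial manifest on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"
    t0 = time.perf_counter()
    logger.info("run_pipeline: seed=%d out_dir=%s", config.seed, out_dir)

    try:
        stage = "load"
        table, input_checksum = _load_table(config)
        pooled = pool_samples(table)
        logger.info(
            "load: %d taxa x %d samples, %d reads (%.1fs)",
            table.n_taxa, table.n_samples, int(pooled.sum()),
            time.perf_counter() - t0,
        )

        stage = "diversity"
        div = diversity_summary(table, orders=config.orders)
        path = out_dir / "diversity.csv"
        div.to_csv(path, index=False)
        outputs.append(path)

        stage = "tac"
        for a in config.orders:
            curve = smoothed_tac(
                table, a, n_perm=config.n_perm, seed=config.seed,
            )
            import pandas as pd

            path = out_dir / f"tac_a{a:g}.csv"
            pd.DataFrame(
                {"step": curve.steps, "mean": curve.mean, "sd": curve.sd}
            ).to_csv(path, index=False)
            outputs.append(path)
        logger.info("tac: %d orders x %d permutations (%.1fs)",
                    len(config.orders), config.n_perm, time.perf_counter() - t0)

        stage = "depth"
        result = depth_analysis(
            pooled,
            depths=config.depths,
            orders=config.orders,
            reps=config.reps,
            seed=config.seed,
            window_frac=config.window_frac,
            tol=config.tol,
        )
        import pandas as pd

        rows = []
        for a in result.orders:
            for r in range(result.reps):
                for j, d in enumerate(result.depths):
                    rows.append(
                        {"order_a": a, "rep": r, "depth": int(d),
                         "hill_number": result.values[a][r, j]}
                    )
        path = out_dir / "depth_analysis.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs.append(path)
        path = out_dir / "stability.json"
        _write_json(path, {
            "depths": [int(d) for d in result.depths],
            "reps": result.reps,
            "window_frac": result.window_frac,
            "tol": result.tol,
            "stability_depth": {
                f"{a:g}": result.stability_depth[a] for a in result.orders
            },
        })
        outputs.append(path)
        logger.info("depth: grid %s (%.1fs)",
                    [int(d) for d in result.depths], time.perf_counter() - t0)

        stage = "rad"
        fits = [fit_lognormal(pooled), fit_zipf(pooled)]
        selected = select_model(fits)
        deviation = deviation_test(
            pooled, n_boot=config.n_boot, seed=config.seed,
        )
        path = out_dir / "rad_fits.csv"
        pd.DataFrame(
            [{"model": f.model, "loglik": f.loglik, "aic": f.aic,
              "n_taxa": f.n_taxa, "n_params": f.n_params,
              "degenerate": f.degenerate,
              **{f"param_{k}": v for k, v in f.params.items()}}
             for f in fits]
        ).to_csv(path, index=False)
        outputs.append(path)
        path = out_dir / "rad.json"
        _write_json(path, {
            "fits": [
                {"model": f.model, "params": f.params, "loglik": f.loglik,
                 "aic": f.aic, "n_taxa": f.n_taxa, "n_params": f.n_params,
                 "degenerate": f.degenerate}
                for f in fits
            ],
            "selected_model": selected.model,
            "aic_tie": selected.aic_tie,
            "deviation": {"model": "lognormal", "D": deviation.D,
                          "p_value": deviation.p_value,
                          "n_boot": deviation.n_boot},
        })
        outputs.append(path)
        logger.info("rad: selected=%s D=%.4f p=%.4g (%.1fs)",
                    selected.model, deviation.D, deviation.p_value,
                    time.perf_counter() - t0)
    except Exception as exc:
        manifest = _manifest(config, outputs, None,
                             status=f"failed at stage {stage}: {exc}")
        _write_json(out_dir / "manifest.json", manifest)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = _manifest(config, outputs, input_checksum, status="ok")
    _write_json(out_dir / "manifest.json", manifest)
    logger.info("run_pipeline: done (%.1fs)", time.perf_counter() - t0)
    return manifest


def _manifest(config: RunConfig, outputs: list[Path],
              input_checksum: str | None, status: str) -> dict:
    return {
        "status": status,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "input_sha256": input_checksum,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
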