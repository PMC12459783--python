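"""Panel CSV readers/writers, run configuration and run manifests."""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rates_smr import CountPanel

__all__ = ["read_panel_csv", "write_panel_csv", "RunConfig", "write_manifest",
           "child_seed"]

REQUIRED_COLUMNS = ("area_id", "year", "count", "population")


def read_panel_csv(path) -> CountPanel:
    """Read a long-format panel CSV with columns area_id, year, count, population.

    The panel must be rectangular: every (area, year) combination present
    exactly once. An optional ``expected`` column fills E.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {missing}")
    df["area_id"] = df["area_id"].astype(str)
    areas = sorted(df["area_id"].unique())
    years = sorted(int(y) for y in df["year"].unique())
    n, T = len(areas), len(years)
    if len(df) != n * T:
        raise ValueError(f"ragged panel: {len(df)} rows, expected {n * T}")
    a_idx = {a: i for i, a in enumerate(areas)}
    y_idx = {y: t for t, y in enumerate(years)}
    Y = np.full((n, T), -1, dtype=float)
    P = np.zeros((n, T))
    E = np.full((n, T), np.nan) if "expected" in df.columns else None
    for row in df.itertuples(index=False):
        i, t = a_idx[str(row.area_id)], y_idx[int(row.year)]
        if Y[i, t] >= 0:
            raise ValueError(f"duplicate cell (area {row.area_id}, year {row.year})")
        Y[i, t] = row.count
        P[i, t] = row.population
        if E is not None:
            E[i, t] = row.expected
    holes = np.argwhere(Y < 0)
    if holes.size:
        i, t = holes[0]
        raise ValueError(f"missing cell (area {areas[i]}, year {years[t]})")
    if np.any(Y != np.round(Y)) or np.any(Y < 0):
        raise ValueError("counts must be non-negative integers")
    return CountPanel(areas=tuple(areas), years=tuple(years),
                      Y=Y.astype(int), P=P, E=E)


def write_panel_csv(panel: CountPanel, path) -> None:
    rows = {
        "area_id": np.repeat(panel.areas, panel.n_years),
        "year": np.tile(panel.years, panel.n_areas),
        "count": panel.Y.ravel(),
        "population": panel.P.ravel(),
    }
    if panel.E is not None:
        rows["expected"] = panel.E.ravel()
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run configuration (paths resolved at load time)."""

    panel_csv: str
    adjacency: str | None = None        # edge list / GAL path
    geojson: str | None = None
    geojson_id_property: str | None = None
    rate_scale: float = 10_000.0
    weight_style: str = "row_standardized"
    likelihood: str = "negbin"
    interaction: str = "IV"
    chains: int = 2
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0
    output_dir: str = "carst_output"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        cfg = cls(**raw)
        if not Path(cfg.panel_csv).exists():
            raise FileNotFoundError(cfg.panel_csv)
        for p in (cfg.adjacency, cfg.geojson):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def child_seed(master_seed: int, stream: str) -> int:
    """Deterministic named child seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def write_manifest(out_dir, stage: str, config: dict, seed: int,
                   inputs: dict | None = None, started: float | None = None) -> Path:
    """JSON sidecar recording config, seed, input hashes and wall time."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    import carst

    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "input_hashes": hashes,
        "version": carst.__version__,
        "wall_time_s": None if started is None else round(time.time() - started, 3),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
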