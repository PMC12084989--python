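"""Cohort CSV reading/validation, run configuration and manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, SyntheticCohort
from .ordinal import NetworkSpec, TrainConfig

__all__ = ["ColumnMapping", "RunConfig", "read_cohort", "write_manifest"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnMapping:
    """Names of the covariate and label columns in a cohort CSV.

    When ``oxi_cols``/``meta_cols`` are None, columns prefixed ``oxi_`` /
    ``meta_`` are used in file order.
    """

    oxi_cols: tuple[str, ...] | None = None
    meta_cols: tuple[str, ...] | None = None
    label_col: str = "label"


def read_cohort(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    n_categories: int | None = None,
) -> SyntheticCohort:
    """Read and validate a cohort CSV.

    Rows with missing values are dropped (count logged); labels must be
    integers. Column lookup is name-based, so file column order is
    irrelevant. Returns a :class:`SyntheticCohort` whose spec records only
    structural information (no true parameters are known for external
    data).
    """
    mapping = mapping or ColumnMapping()
    df = pd.read_csv(path)
    def discovered(prefix: str) -> list[str]:
        # name-based and order-independent: sort on the numeric suffix
        found = [c for c in df.columns if c.startswith(prefix)]
        return sorted(found, key=lambda c: (len(c), c))

    oxi_cols = list(mapping.oxi_cols or discovered("oxi_"))
    meta_cols = list(mapping.meta_cols or discovered("meta_"))
    if not oxi_cols or not meta_cols:
        raise ValueError("oxidation and metabolism column sets must be non-empty")
    needed = oxi_cols + meta_cols + [mapping.label_col]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    if mapping.label_col in oxi_cols + meta_cols:
        raise ValueError("label column must be distinct from covariate columns")
    n0 = len(df)
    df = df.dropna(subset=needed)
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d rows with missing values from %s", dropped, path)
    labels_raw = df[mapping.label_col]
    as_float = labels_raw.to_numpy(float)
    nonint = np.flatnonzero(as_float != np.floor(as_float))
    if nonint.size:
        raise ValueError(
            f"non-integer label at row {int(nonint[0])}: {as_float[nonint[0]]!r}"
        )
    y = as_float.astype(np.int64)
    J = int(y.max()) + 1 if n_categories is None else n_categories
    census = {int(g): int(c) for g, c in zip(*np.unique(y, return_counts=True))}
    logger.info("label census for %s: %s", path, census)
    spec = CohortSpec(
        n_samples=len(df),
        n_categories=J,
        seed=0,
        alpha_true=tuple(np.linspace(1.0, -1.0, J - 1)),
        beta_oxi_true=tuple(0.0 for _ in oxi_cols),
        beta_meta_true=tuple(0.0 for _ in meta_cols),
        n_shared=0,  # unknown overlap structure for external data
    )
    return SyntheticCohort(
        X_oxi=df[oxi_cols].to_numpy(float),
        X_meta=df[meta_cols].to_numpy(float),
        y=y,
        spec=spec,
    )


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (YAML file + flag overrides)."""

    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    normalizer: str = "minmax"
    hsi_level: float = 0.95
    hsi_method: str = "grid"
    hsi_resolution: int = 512
    bootstrap_B: int = 200
    bootstrap_seed: int = 0
    mapping: ColumnMapping = field(default_factory=ColumnMapping)

    @classmethod
    def from_yaml(cls, path: str | Path | None, **overrides) -> "RunConfig":
        raw: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        net = raw.pop("network", {})
        if "hidden_widths" in net:
            net["hidden_widths"] = tuple(net["hidden_widths"])
            net.setdefault("n_hidden_layers", len(net["hidden_widths"]))
        train = raw.pop("train", {})
        mapping = raw.pop("mapping", {})
        for key in ("oxi_cols", "meta_cols"):
            if mapping.get(key) is not None:
                mapping[key] = tuple(mapping[key])
        return cls(
            network=NetworkSpec(**net),
            train=TrainConfig(**train),
            mapping=ColumnMapping(**mapping),
            **raw,
        )

    def to_dict(self) -> dict:
        return {
            "network": {
                "n_hidden_layers": self.network.n_hidden_layers,
                "hidden_widths": list(self.network.hidden_widths),
                "activation": self.network.activation,
            },
            "train": dict(self.train.__dict__),
            "normalizer": self.normalizer,
            "hsi_level": self.hsi_level,
            "hsi_method": self.hsi_method,
            "hsi_resolution": self.hsi_resolution,
            "bootstrap_B": self.bootstrap_B,
            "bootstrap_seed": self.bootstrap_seed,
            "mapping": {
                "oxi_cols": list(self.mapping.oxi_cols) if self.mapping.oxi_cols else None,
                "meta_cols": list(self.mapping.meta_cols) if self.mapping.meta_cols else None,
                "label_col": self.mapping.label_col,
            },
        }


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a reproducibility manifest: config, its hash, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": digest,
    }
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
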