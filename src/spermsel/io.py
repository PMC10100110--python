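"""Configuration files, run manifests and tabular output.

All artifacts are small plain-text tables (TSV, floats at full precision)
plus a JSON manifest. The manifest records the config snapshot, the master
seed and the seed-derivation scheme; together with the package version it
suffices to reproduce every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import SimulationConfig
from .experiment import ExperimentResult

__all__ = ["RunManifest", "load_config", "save_config", "write_grid_tables"]

FLOAT_FORMAT = "%.17g"  # round-trips any IEEE double

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}

SEED_SCHEME = (
    "replicate rng = default_rng(SeedSequence(master_seed, spawn_key=(cell, replicate))); "
    "cell indexes itertools.product(sigma_F_levels, partner_levels); "
    "the seed column reads master:cell:replicate"
)


def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML or JSON file.

    Defaults are filled for absent fields; unknown keys are an error (JSON
    is parsed by the YAML loader, of which it is a subset).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config fields, got {type(data).__name__}")
    unknown = sorted(set(data) - _CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    try:
        return SimulationConfig(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: {err}") from err


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Provenance of one run: config, seeds, version, timestamp."""

    config: dict
    master_seed: int
    n_replicates: int
    sigma_F_levels: list = field(default_factory=list)
    partner_levels: list = field(default_factory=list)
    quantile_probs: list = field(default_factory=lambda: [0.025, 0.975])
    seed_scheme: str = SEED_SCHEME
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_grid_tables(result: ExperimentResult, out_dir) -> dict[str, Path]:
    """Write gradients.tsv, summary.tsv, effects.tsv and manifest.json.

    Returns the mapping of table name to written path. Table contents are
    deterministic for a fixed master seed; only the manifest carries a
    timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gradients": out / "gradients.tsv",
        "summary": out / "summary.tsv",
        "effects": out / "effects.tsv",
        "manifest": out / "manifest.json",
    }
    _write_tsv(result.gradients, paths["gradients"])
    _write_tsv(result.summary(), paths["summary"])
    # the ANOVA needs >= 2 levels of each factor; single-condition runs skip it
    if (
        result.gradients["sigma_F"].nunique() >= 2
        and result.gradients["n_partners"].nunique() >= 2
    ):
        effects = result.eta_squared(include_residual=True).rename_axis("term").reset_index()
        _write_tsv(effects, paths["effects"])
    else:
        del paths["effects"]
    manifest = RunManifest(
        config=result.base_config.to_dict() if result.base_config else {},
        master_seed=result.master_seed,
        n_replicates=int(result.gradients.groupby(["sigma_F", "n_partners"]).size().iloc[0]),
        sigma_F_levels=sorted(result.gradients["sigma_F"].unique().tolist()),
        partner_levels=sorted(int(k) for k in result.gradients["n_partners"].unique()),
        quantile_probs=list(result.quantile_probs),
    )
    manifest.write(paths["manifest"])
    return paths
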