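"""Run configuration: protocol defaults, TOML resolution, provenance records.

The defaults are the protocol constants used throughout the toolkit:
up to 500 conformers sampled per compound, the 10 best-overlaying kept,
200 refined poses scored, 5 submitted; 5 Å interface, 8.5 Å nonbonded and
10.5 Å contact cutoffs; 2.5 Å acceptable-pose threshold; score weights
1.0/0.1/1.0/0.1; affinity averaging over the top 10 poses; 10 µM binder
threshold.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields

from .errors import InputError

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    max_confs: int = 500
    top_confs: int = 10
    n_poses: int = 200
    submission_size: int = 5
    interface_cutoff: float = 5.0
    nonbonded_cutoff: float = 8.5
    contact_cutoff: float = 10.5
    acceptable_rmsd: float = 2.5
    score_weights: tuple[float, float, float, float] = (1.0, 0.1, 1.0, 0.1)
    affinity_top_k: int = 10
    binder_threshold_molar: float = 10e-6
    seed: int = 0

    @property
    def n_restarts(self) -> int:
        """Refinement restarts per selected conformer."""
        return max(1, self.n_poses // max(1, self.top_confs))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        """Record stamped into every output file."""
        return {
            "toolkit_version": __version__,
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}


def resolve_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults < TOML file < explicit overrides.

    Unknown keys and type mismatches are errors naming the offending key.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})

    clean: dict = {}
    for key, value in values.items():
        if key not in _FIELD_TYPES:
            raise InputError(f"unknown configuration key {key!r}")
        clean[key] = _coerce(key, value)
    return RunConfig(**clean)


def _coerce(key: str, value):
    if key == "score_weights":
        try:
            weights = tuple(float(v) for v in value)
        except (TypeError, ValueError):
            raise InputError(f"configuration key 'score_weights' must be 4 numbers")
        if len(weights) != 4:
            raise InputError("configuration key 'score_weights' must have 4 entries")
        return weights
    if key in ("max_confs", "top_confs", "n_poses", "submission_size",
               "affinity_top_k", "seed"):
        if isinstance(value, bool) or not isinstance(value, int):
            raise InputError(f"configuration key {key!r} must be an integer")
        return value
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise InputError(f"configuration key {key!r} must be a number")
    return float(value)
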