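"""Readers, writers and run configuration.

Formats are plain text throughout: trial tables and posterior draws as CSV,
configuration as YAML (or JSON — YAML is a superset here), diagnostics and
recovery reports as JSON.  Positions are signed cm, negative = left of the
midline; condition labels are A / T / AT; responses are 0 (left) / 1 (right).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import HyperpriorSpec, StimulusBatch, aggregate_trials
from .psychometric import CONDITIONS
from .sampler import PosteriorDraws, RunSettings

__all__ = ["Dataset", "RunConfig", "read_trials", "write_trials", "save_draws", "load_draws"]


@dataclass
class Dataset:
    """A single experiment's trial-level (or pre-aggregated) data.

    ``trials`` always carries canonical columns subject / condition / x_cm /
    response, plus n and y instead of response when pre-aggregated.
    """

    experiment: int
    trials: pd.DataFrame
    provenance: str = ""
    aggregated: bool = False

    def batches(self) -> list[StimulusBatch]:
        if not self.aggregated:
            return aggregate_trials(self.trials)
        from .psychometric import ConditionFlags

        order = pd.unique(self.trials["subject"])
        idx = {s: i for i, s in enumerate(order)}
        return [
            StimulusBatch(
                subject_index=idx[row.subject],
                flags=ConditionFlags.from_label(row.condition),
                x=float(row.x_cm),
                n=int(row.n),
                y=int(row.y),
            )
            for row in self.trials.itertuples(index=False)
        ]

    @property
    def n_subjects(self) -> int:
        return int(self.trials["subject"].nunique())


@dataclass
class RunConfig:
    """End-to-end run configuration with every stochastic stage's seed recorded."""

    experiment: int = 2
    hyperpriors: HyperpriorSpec | None = None
    chains: int = 4
    warmup: int = 2500
    draws: int = 2500
    target_accept: float = 0.95
    n_subjects: int = 20
    trials_per_condition: int = 100
    psi_n_beta: int = 31
    psi_n_lam: int = 21
    contrast_n_draws: int = 100_000
    curve_n_functions: int = 10_000
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hyperpriors is None:
            self.hyperpriors = HyperpriorSpec.for_experiment(self.experiment)

    def sampler_settings(self) -> RunSettings:
        return RunSettings(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.seed,
            target_accept=self.target_accept,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hyperpriors"] = self.hyperpriors.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("hyperpriors"), dict):
            d["hyperpriors"] = HyperpriorSpec.from_dict(d["hyperpriors"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def read_trials(
    path: str | Path,
    experiment: int | None = None,
    column_map: dict[str, str] | None = None,
) -> Dataset:
    """Read a stimulus-response CSV into a validated :class:`Dataset`.

    Expects trial-level columns (subject, condition, x_cm, response) or
    pre-aggregated ones (subject, condition, x_cm, n, y).  ``column_map``
    renames source columns to canonical names ({"source_name": "x_cm"}, ...).
    Unrecognized columns are kept but ignored.  Raises a schema error naming
    the first offending row on invalid condition labels, responses outside
    {0, 1}, or y > n.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    aggregated = {"n", "y"}.issubset(df.columns) and "response" not in df.columns
    needed = {"subject", "condition", "x_cm"} | ({"n", "y"} if aggregated else {"response"})
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns {sorted(missing)}; provide a column_map")

    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"row {i}: unknown condition label {df['condition'].iloc[i]!r}")
    if aggregated:
        bad = df["y"] > df["n"]
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"row {i}: y={df['y'].iloc[i]} exceeds n={df['n'].iloc[i]}")
    else:
        bad = ~df["response"].isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"row {i}: response {df['response'].iloc[i]!r} outside {{0, 1}}")
    df["x_cm"] = df["x_cm"].astype(float)

    if experiment is None:
        if "experiment" in df.columns:
            tags = df["experiment"].unique()
            if len(tags) > 1:
                raise ValueError(f"file mixes experiment tags {sorted(tags)}")
            experiment = int(tags[0])
        else:
            # infer from the stimulus range: beyond 2 cm implies the wide design
            experiment = 2 if df["x_cm"].abs().max() > 2.0 + 1e-9 else 1
    return Dataset(experiment=experiment, trials=df, provenance=str(path), aggregated=aggregated)


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_draws(draws: PosteriorDraws, path: str | Path) -> None:
    """Persist draws as a wide CSV: chain, draw, then one column per scalar."""
    scalars = draws.scalar_params()
    chains, per = draws.chain_count, draws.draws_per_chain
    out = {
        "chain": np.repeat(np.arange(chains), per),
        "draw": np.tile(np.arange(per), chains),
    }
    for name, a in scalars.items():
        out[name] = a.reshape(-1)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(out).to_csv(path, index=False)


def load_draws(path: str | Path) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from a wide CSV written by :func:`save_draws`.

    Sampler telemetry (energy, divergences) is not persisted in the CSV; the
    loaded object carries empty telemetry and supports the posterior-analysis
    operations (summaries, contrasts, curves), not the diagnostics gate.
    """
    df = pd.read_csv(path)
    chains = int(df["chain"].max()) + 1
    per = int(df["draw"].max()) + 1
    if len(df) != chains * per:
        raise ValueError("draw table is ragged; expected a full chains x draws grid")
    df = df.sort_values(["chain", "draw"])
    params: dict[str, np.ndarray] = {}
    subject_cols: dict[str, list[str]] = {}
    for col in df.columns:
        if col in ("chain", "draw"):
            continue
        if col.endswith("]") and "[" in col:
            base = col[: col.index("[")]
            subject_cols.setdefault(base, []).append(col)
        else:
            params[col] = df[col].to_numpy().reshape(chains, per)
    for base, cols in subject_cols.items():
        cols = sorted(cols, key=lambda c: int(c[c.index("[") + 1 : -1]))
        params[base] = np.stack(
            [df[c].to_numpy().reshape(chains, per) for c in cols], axis=2
        )
    n_subj = max((a.shape[2] for a in params.values() if a.ndim == 3), default=0)
    empty = np.zeros((chains, 0))
    return PosteriorDraws(
        chain_count=chains,
        draws_per_chain=per,
        params=params,
        unconstrained=np.zeros((chains, per, 0)),
        energy=empty,
        divergences=np.zeros((chains, 0), dtype=bool),
        treedepth_hits=np.zeros((chains, 0), dtype=bool),
        accept_stat=empty,
        n_subjects=n_subj,
    )


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
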