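"""End-to-end pipeline: diversity -> temporal beta -> TLA -> ordination ->
correlation screens, with one output artifact per display item and a
provenance stamp (resolved configuration + package version) embedded in
every file.

Determinism contract: one global seed, deterministically split per stage
with :class:`numpy.random.SeedSequence`, and no timestamps in outputs, so
the same configuration and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import alpha_diversity_table, temporal_beta_table, texture_summary
from .exceptions import LagbetaError
from .io import align, read_chemistry, read_fingerprint, read_metadata
from .ordination import cca, forward_select, permutation_test, variance_partition
from .screens import pearson_screen
from .timelag import site_lag_pairs, tla_table
from .diversity import composite_profiles

STAGES = ("diversity", "temporal_beta", "tla", "ordination", "correlations")

DEFAULT_VARIABLES = ("pH", "nh4", "no3", "om", "clay", "moisture")


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run (recorded in every output)."""

    fingerprint: str
    metadata: str
    chemistry: str | None = None
    out_dir: str = "results"
    replicate_policy: str = "replicate_mean"
    metric: str = "hellinger"
    time_unit: str = "months"
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    variables: tuple = DEFAULT_VARIABLES
    distance_scale: float = 1.0
    overall_mode: str = "pooled"
    permutation_scheme: str = "relabel"
    forward_selection: bool = True

    def provenance(self) -> dict:
        out = asdict(self)
        out["variables"] = ",".join(self.variables)
        out["lagbeta_version"] = __version__
        return out


def parse_config(path) -> dict:
    """Flat ``key = value`` text file mirroring the CLI flags."""
    values: dict[str, str] = {}
    for line_no, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise LagbetaError(f"{path}:{line_no}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        values[key] = value
    return values


def config_from_file(path, **overrides) -> RunConfig:
    raw = parse_config(path)
    kwargs: dict = {}
    casts = {
        "n_perm": int,
        "seed": int,
        "alpha": float,
        "distance_scale": float,
        "forward_selection": lambda v: v.lower() in ("1", "true", "yes"),
        "variables": lambda v: tuple(x.strip() for x in v.split(",") if x.strip()),
    }
    for key, value in raw.items():
        if key not in RunConfig.__dataclass_fields__:
            raise LagbetaError(f"unknown config key {key!r}")
        kwargs[key] = casts.get(key, str)(value)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)


def _write_csv(frame: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, lineterminator="\n")


def run_full_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in order and write one artifact per display item.

    Returns a mapping from stage name to written path.  Any stage error is
    re-raised annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    seeds = {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }

    fp = read_fingerprint(config.fingerprint, normalize=True)
    md = read_metadata(config.metadata)
    chem = read_chemistry(config.chemistry) if config.chemistry else None
    data = align(fp, md, chem)
    written: dict[str, Path] = {}

    stage = "diversity"
    try:
        alpha = alpha_diversity_table(data.fingerprint)
        alpha = alpha.join(data.metadata[["site", "date", "replicate", "texture"]])
        path = out_dir / "alpha_diversity.csv"
        _write_csv(alpha, path, prov)
        written[stage] = path

        stage = "temporal_beta"
        beta = temporal_beta_table(data.fingerprint, data.metadata, policy=config.replicate_policy)
        summary = texture_summary(beta, "beta")
        summary.index = [f"texture:{t}" for t in summary.index]
        summary = summary.rename(columns={"mean": "beta"})
        beta_out = pd.concat([beta, summary])
        path = out_dir / "temporal_beta.csv"
        _write_csv(beta_out, path, prov)
        written[stage] = path

        stage = "tla"
        comps = composite_profiles(data.fingerprint, data.metadata, policy=config.replicate_policy)
        tla = tla_table(
            comps,
            metric=config.metric,
            time_unit=config.time_unit,
            n_perm=config.n_perm,
            seed=seeds["tla"],
            distance_scale=config.distance_scale,
            overall_mode=config.overall_mode,
            scheme=config.permutation_scheme,
        )
        path = out_dir / "tla.csv"
        _write_csv(tla, path, prov)
        written[stage] = path

        stage = "ordination"
        if data.chemistry is not None:
            path = out_dir / "cca.json"
            _write_ordination(data, config, seeds["ordination"], prov, path)
            written[stage] = path

            stage = "correlations"
            screen = _correlation_screens(data, beta, tla, config)
            path = out_dir / "correlations.csv"
            _write_csv(screen.set_index(["level", "biotic", "abiotic"]), path, prov)
            written[stage] = path
    except LagbetaError as exc:
        raise LagbetaError(f"stage {stage!r} failed: {exc}") from exc
    return written


def _composite_chemistry(data, variables) -> pd.DataFrame:
    """Chemistry averaged to the (site, date) composite level."""
    chem = data.chemistry.join(data.metadata[["site", "date"]])
    have = [v for v in variables if v in chem.columns]
    if not have:
        raise LagbetaError(f"none of the requested variables {variables} present in chemistry")
    return chem.groupby(["site", "date"])[have].mean()


def _jsonable_scores(frame: pd.DataFrame) -> dict:
    out = frame.round(10).copy()
    out.index = ["/".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in out.index]
    return out.to_dict(orient="split")


def _write_ordination(data, config: RunConfig, seed: int, prov: dict, path: Path) -> None:
    comps = composite_profiles(data.fingerprint, data.metadata, policy=config.replicate_policy)
    X = _composite_chemistry(data, config.variables).reindex(comps.index).dropna(axis=1, how="any")
    dropped = [v for v in config.variables if v not in X.columns]
    result = cca(comps, X)
    f_obs, p_all = permutation_test(comps, X, n_perm=config.n_perm, seed=seed)
    partition = variance_partition(comps, X)
    payload = {
        "provenance": prov,
        "variables_used": list(X.columns),
        "variables_dropped_missing": dropped,
        "total_inertia": result.total_inertia,
        "constrained_inertia": result.constrained_inertia,
        "explained_fraction": result.explained_fraction,
        "eigenvalues": result.eigenvalues.tolist(),
        "pseudo_f": f_obs,
        "p_permutation": p_all,
        "variance_partition": {
            "total_explained": partition.total_explained,
            "unique_fractions": partition.unique_fractions,
            "residual": partition.residual,
        },
        "site_scores_lc": _jsonable_scores(result.site_scores_lc),
        "band_scores": _jsonable_scores(result.band_scores),
        "biplot_scores": _jsonable_scores(result.biplot_scores),
    }
    if config.forward_selection:
        trace = forward_select(
            comps, X, alpha=config.alpha, n_perm=config.n_perm, seed=seed + 1
        )
        payload["forward_selection"] = {
            "selected": trace.selected,
            "steps": [
                {
                    "variable": s.variable,
                    "added_fraction": s.added_fraction,
                    "p_value": s.p_value,
                    "retained": s.retained,
                }
                for s in trace.steps
            ],
            "stopping_reason": trace.stopping_reason,
        }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def _correlation_screens(data, beta: pd.DataFrame, tla: pd.DataFrame, config: RunConfig):
    """Two-level Pearson screen mirroring the classical correlation table.

    Site-by-date level: mean alpha diversity per composite against composite
    chemistry.  Site level: temporal beta and the TLA slope against site-mean
    chemistry.
    """
    chem_sd = _composite_chemistry(data, config.variables)
    alpha = alpha_diversity_table(data.fingerprint).join(data.metadata[["site", "date"]])
    alpha_sd = alpha.groupby(["site", "date"])[["shannon_h", "richness"]].mean()
    screen_sd = pearson_screen(alpha_sd, chem_sd)
    screen_sd.insert(0, "level", "site_date")

    chem_site = chem_sd.groupby(level="site").mean()
    biotic_site = beta[["beta"]].join(tla["slope"].rename("tla_slope"), how="inner")
    screens = [screen_sd]
    if len(biotic_site) >= 3:
        screen_site = pearson_screen(biotic_site, chem_site)
        screen_site.insert(0, "level", "site")
        screens.append(screen_site)
    return pd.concat(screens, ignore_index=True)
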