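"""End-to-end study orchestration with staged, serialized artifacts.

The pipeline mirrors the two-stage design: (1) select the cross-basis
dimensions by summed QAIC on the total-population stream, (2) fit each
unit's conditional quasi-Poisson model, (3) reduce to overall cumulative
coefficients and pool by multivariate meta-analysis, (4) produce pooled and
subgroup RR curves against a shared reference temperature, and (5) compute
attributable fractions with Monte-Carlo intervals from the per-unit BLUPs.

Each stage reads only the serialized outputs of prior stages (CSV for data
and tables, JSON for fits and pooled results, YAML for configuration), so
any stage can be re-run in isolation and the whole run is reproducible from
the configuration and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attributable import study_af
from .casecrossover import (
    ConditionalQuasiPoisson,
    StratifiedFit,
    StratumAssignment,
    assign_strata,
    select_spec,
    unit_design,
)
from .crossbasis import CrossBasis
from .meta import MetaResult, MVMeta
from .reduction import ReducedCurve, center_curve, find_mmt, reduce_overall, rr_curve
from .synthetic import make_study, true_attributable_fraction, write_study

logger = logging.getLogger("heatlag")

REQUIRED_COLUMNS = ("date", "count", "temp_c", "humidity_pct", "rain_mm", "sunshine_h")
WEATHER_COLUMNS = ("temp_c", "humidity_pct", "rain_mm", "sunshine_h")


@dataclass
class DailySeries:
    """One unit's aligned daily dates, counts, and weather covariates."""

    unit_id: str
    dates: pd.DatetimeIndex
    counts: np.ndarray
    weather: pd.DataFrame
    subgroups: dict = field(default_factory=dict)


def read_daily_series(path, max_interpolate: int = 2) -> DailySeries:
    """Read and validate one unit's CSV.

    Dates must be unique and consecutive; counts nonnegative integers.
    Missing weather values are linearly interpolated across runs of up to
    ``max_interpolate`` consecutive days; longer runs stay missing and the
    fitting stage drops every lag window touching them.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    dup = dates[dates.duplicated()]
    if len(dup):
        raise ValueError(f"{path.name}: duplicated date {dup.iloc[0].date()}")
    order = np.argsort(dates.values)
    df = df.iloc[order].reset_index(drop=True)
    dates = pd.DatetimeIndex(dates.values[order])
    gaps = np.flatnonzero(np.diff(dates.values).astype("timedelta64[D]") != np.timedelta64(1, "D"))
    if gaps.size:
        raise ValueError(f"{path.name}: missing date after {dates[gaps[0]].date()}")
    counts = pd.to_numeric(df["count"], errors="raise").to_numpy()
    if (counts < 0).any():
        bad = dates[np.flatnonzero(counts < 0)[0]].date()
        raise ValueError(f"{path.name}: negative count on {bad}")
    weather = df[list(WEATHER_COLUMNS)].astype(float).copy()
    # fill short gaps entirely, leave longer runs entirely missing
    for col in WEATHER_COLUMNS:
        v = weather[col]
        if not v.isna().any():
            continue
        runs = v.isna().astype(int).groupby(v.notna().cumsum()).transform("sum")
        filled = v.interpolate(limit_area="inside")
        weather[col] = filled.where(~(v.isna() & (runs > max_interpolate)), np.nan)
    weather.index = dates
    subgroups = {
        c.removeprefix("count_"): pd.to_numeric(df[c]).to_numpy()
        for c in df.columns
        if c.startswith("count_")
    }
    for name, sub in subgroups.items():
        if (sub < 0).any():
            raise ValueError(f"{path.name}: negative subgroup count in {name}")
    return DailySeries(
        unit_id=path.stem, dates=dates, counts=counts, weather=weather,
        subgroups=subgroups,
    )


def validate_subgroups(series: DailySeries, axes: list[tuple[str, str]]) -> None:
    """Check each subgroup pair sums to the total count on every day."""
    for a, b in axes:
        if a not in series.subgroups or b not in series.subgroups:
            continue
        total = series.subgroups[a] + series.subgroups[b]
        bad = np.flatnonzero(total != series.counts)
        if bad.size:
            raise ValueError(
                f"{series.unit_id}: subgroup counts {a}+{b} do not sum to the "
                f"total on {series.dates[bad[0]].date()}"
            )


def _stream_series(series: DailySeries, stream: str) -> DailySeries:
    if stream == "total":
        return series
    return DailySeries(
        unit_id=series.unit_id,
        dates=series.dates,
        counts=series.subgroups[stream],
        weather=series.weather,
    )


def fit_unit(series: DailySeries, spec, max_lag: int = 21) -> StratifiedFit:
    """Fit one unit: cross-basis + 5-df confounder splines, stratified."""
    X, y, strata, usable = unit_design(series, spec)
    est = ConditionalQuasiPoisson().fit(
        X[usable], y[usable], strata=StratumAssignment(strata.codes[usable], strata.keys)
    )
    return StratifiedFit.from_estimator(est, spec=spec)


def _unit_spec(series: DailySeries, lag_knots: int, var_df: int, max_lag: int):
    cb = CrossBasis(var_df=var_df, lag_knots=lag_knots, max_lag=max_lag)
    cb.fit(series.weather["temp_c"].to_numpy(float))
    return cb.spec_


def study_spec(series_list, lag_knots: int, var_df: int, max_lag: int):
    """Shared cross-basis spec over the pooled temperature distribution."""
    from .casecrossover import shared_crossbasis_spec

    return shared_crossbasis_spec(series_list, lag_knots, var_df, max_lag)


def fitted_day_data(series: DailySeries, spec):
    """Temps and counts on the days that entered the fit (burn-in dropped)."""
    X, y, _, usable = unit_design(series, spec)
    return series.weather["temp_c"].to_numpy(float)[usable], y[usable]


_fitted_day_data = fitted_day_data


class StudyRunner:
    """Stage-by-stage execution of a full study into an output directory."""

    def __init__(self, config: dict, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.master_seed = int(config.get("seed", 0))
        self.max_lag = int(config.get("max_lag", 21))
        self.band = tuple(config.get("percentile_band", (1.0, 99.0)))
        self.n_sim = int(config.get("n_sim", 5000))
        self.subgroup_axes = [tuple(a) for a in config.get("subgroup_axes", [])]

    # -- stage 0: data ----------------------------------------------------
    def stage_data(self) -> None:
        data_dir = self.outdir / "data"
        if "generator" in self.config:
            units = make_study(self.config["generator"], self.master_seed)
            write_study(units, self.config["generator"], self.master_seed, data_dir)
            truth = {
                "true_af_units": {
                    u.unit_id: true_attributable_fraction(u, self.band) for u in units
                }
            }
            (self.outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        else:
            data_dir.mkdir(parents=True, exist_ok=True)
            for p in map(Path, self.config["data"]):
                (data_dir / p.name).write_text(p.read_text())
        logger.info("stage data: %d unit files", len(list(data_dir.glob("*.csv"))))

    def _load_series(self) -> list[DailySeries]:
        series = [
            read_daily_series(p) for p in sorted((self.outdir / "data").glob("*.csv"))
        ]
        for s in series:
            validate_subgroups(s, self.subgroup_axes)
        return series

    # -- stage 1: spec selection ------------------------------------------
    def stage_select_spec(self) -> None:
        series = self._load_series()
        if "spec" in self.config:
            lag_knots = int(self.config["spec"]["lag_knots"])
            var_df = int(self.config["spec"]["var_df"])
            audit = pd.DataFrame(
                [{"lag_knots": lag_knots, "var_df": var_df, "qaic_sum": np.nan, "valid": True}]
            )
        else:
            grid = self.config.get("spec_grid", {})
            (lag_knots, var_df), audit = select_spec(
                series,
                lag_knots_grid=tuple(grid.get("lag_knots", (1, 2, 3))),
                var_df_grid=tuple(grid.get("var_df", (3, 4, 5))),
                max_lag=self.max_lag,
            )
        (self.outdir / "spec.yaml").write_text(
            yaml.safe_dump({"lag_knots": lag_knots, "var_df": var_df, "max_lag": self.max_lag})
        )
        audit.to_csv(self.outdir / "spec_audit.csv", index=False, float_format="%.6f")
        logger.info("stage select-spec: lag_knots=%d var_df=%d", lag_knots, var_df)

    def _spec_choice(self):
        d = yaml.safe_load((self.outdir / "spec.yaml").read_text())
        return int(d["lag_knots"]), int(d["var_df"])

    def _streams(self, series: list[DailySeries]) -> list[str]:
        streams = ["total"]
        common = set.intersection(*(set(s.subgroups) for s in series)) if series else set()
        streams += sorted(common)
        return streams

    # -- stage 2: per-unit fits -------------------------------------------
    def stage_fit(self) -> None:
        series = self._load_series()
        lag_knots, var_df = self._spec_choice()
        spec = study_spec(series, lag_knots, var_df, self.max_lag)
        fits = {}
        for stream in self._streams(series):
            fits[stream] = {}
            for s in series:
                sub = _stream_series(s, stream)
                try:
                    fits[stream][s.unit_id] = fit_unit(sub, spec, self.max_lag).to_dict()
                except (ValueError, np.linalg.LinAlgError) as err:
                    logger.warning("fit failed for %s/%s: %s", stream, s.unit_id, err)
                    fits[stream][s.unit_id] = {"error": str(err)}
        (self.outdir / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
        self._write_gvif(series, spec)
        logger.info("stage fit: %d streams", len(fits))

    def _write_gvif(self, series, spec) -> None:
        """Adjusted GVIF per term from unstratified quasi-Poisson fits on the
        total stream (multicollinearity cannot be assessed conditionally)."""
        from .casecrossover import confounder_design, gvif_check
        from .crossbasis import build_crossbasis

        rows = []
        for s in series:
            cb = build_crossbasis(s.weather["temp_c"].to_numpy(float), spec)
            conf = confounder_design(s.weather)
            usable = cb.complete & np.isfinite(conf).all(axis=1)
            blocks = {
                "temperature_crossbasis": cb.values[usable],
                "humidity": conf[usable, 0:5],
                "rainfall": conf[usable, 5:10],
                "sunshine": conf[usable, 10:15],
            }
            out = gvif_check(np.asarray(s.counts, float)[usable], blocks)
            rows.append({"unit_id": s.unit_id, **out})
        pd.DataFrame(rows).to_csv(
            self.outdir / "gvif.csv", index=False, float_format="%.4f"
        )

    # -- stage 3: reduction + pooling -------------------------------------
    def stage_pool(self) -> None:
        fits = json.loads((self.outdir / "fits.json").read_text())
        pooled = {}
        for stream, unit_fits in fits.items():
            thetas, vcovs, curves = [], [], {}
            for unit_id in sorted(unit_fits):
                d = unit_fits[unit_id]
                if "error" in d:
                    continue
                f = StratifiedFit.from_dict(d)
                curve = reduce_overall(f.coef, f.vcov, f.spec, unit_id=unit_id)
                curves[unit_id] = curve.to_dict()
                thetas.append(curve.theta)
                vcovs.append(curve.vcov)
            if len(thetas) < 2:
                pooled[stream] = {"error": "fewer than 2 fitted units"}
                continue
            meta = MetaResult.from_estimator(
                MVMeta(method=self.config.get("meta_method", "reml")).fit(thetas, vcovs)
            )
            pooled[stream] = {
                "meta": meta.to_dict(),
                "curves": curves,
                "unit_order": sorted(k for k in unit_fits if "error" not in unit_fits[k]),
            }
        (self.outdir / "pooled.json").write_text(json.dumps(pooled, indent=1, sort_keys=True))
        logger.info("stage pool: done")

    # -- stage 4: curves ---------------------------------------------------
    def stage_curves(self) -> None:
        series = self._load_series()
        pooled = json.loads((self.outdir / "pooled.json").read_text())
        all_temps = np.concatenate(
            [s.weather["temp_c"].to_numpy(float) for s in series]
        )
        all_temps = all_temps[np.isfinite(all_temps)]
        p_lo, p_hi = np.percentile(all_temps, self.band)
        grid = np.round(np.arange(np.ceil(p_lo * 10) / 10, p_hi + 0.05, 0.1), 1)

        # shared reference: the total-population pooled curve's MMT
        refs = {}
        for stream, d in pooled.items():
            if "error" in d:
                continue
            meta = MetaResult.from_dict(d["meta"])
            any_curve = ReducedCurve.from_dict(next(iter(d["curves"].values())))
            curve = ReducedCurve(meta.pooled_theta, meta.pooled_vcov, any_curve.var_spec)
            refs[stream] = find_mmt(curve, all_temps, band=self.band)
        shared_ref = refs.get("total")
        rows = []
        for stream, d in sorted(pooled.items()):
            if "error" in d:
                continue
            meta = MetaResult.from_dict(d["meta"])
            any_curve = ReducedCurve.from_dict(next(iter(d["curves"].values())))
            curve = ReducedCurve(meta.pooled_theta, meta.pooled_vcov, any_curve.var_spec)
            ref = shared_ref if shared_ref is not None else refs[stream]
            rr = rr_curve(center_curve(curve, ref), grid)
            rr.insert(0, "stream", stream)
            rr.insert(1, "reference_temp", ref)
            rows.append(rr)
        out = pd.concat(rows, ignore_index=True)
        out.to_csv(self.outdir / "rr_curves.csv", index=False, float_format="%.8f")
        (self.outdir / "references.json").write_text(
            json.dumps({"shared": shared_ref, "per_stream_mmt": refs}, indent=1, sort_keys=True)
        )
        logger.info("stage curves: reference %.1f C", shared_ref)

    # -- stage 5: attributable fractions ----------------------------------
    def stage_af(self) -> None:
        series = self._load_series()
        pooled = json.loads((self.outdir / "pooled.json").read_text())
        fits = json.loads((self.outdir / "fits.json").read_text())
        by_id = {s.unit_id: s for s in series}
        rows = []
        af_seed_root = np.random.SeedSequence(self.master_seed + 1)
        streams = sorted(k for k, d in pooled.items() if "error" not in d)
        seeds = af_seed_root.spawn(len(streams))
        for stream, seed in zip(streams, seeds):
            d = pooled[stream]
            meta = MetaResult.from_dict(d["meta"])
            unit_ids = d["unit_order"]
            blups = meta.blups
            specs, data = [], []
            for uid in unit_ids:
                curve = ReducedCurve.from_dict(d["curves"][uid])
                specs.append(curve.var_spec)
                spec_d = StratifiedFit.from_dict(fits[stream][uid]).spec
                sub = _stream_series(by_id[uid], stream)
                data.append(_fitted_day_data(sub, spec_d))
            res = study_af(
                blups, data, specs, band=self.band, n_sim=self.n_sim,
                seed=int(seed.generate_state(1)[0] % (2**31)), scope=stream,
            )
            rows.append(res.to_dict())
        pd.DataFrame(rows).to_csv(
            self.outdir / "af.csv", index=False, float_format="%.6f"
        )
        logger.info("stage af: %d streams", len(rows))

    # -- stage 6: heterogeneity table --------------------------------------
    def stage_heterogeneity(self) -> None:
        pooled = json.loads((self.outdir / "pooled.json").read_text())
        rows = []
        for stream, d in sorted(pooled.items()):
            if "error" in d:
                continue
            meta = MetaResult.from_dict(d["meta"])
            rows.append(
                {"stream": stream, "q": meta.q, "q_df": meta.q_df,
                 "q_pvalue": meta.q_pvalue, "i2_pct": meta.i2}
            )
        pd.DataFrame(rows).to_csv(
            self.outdir / "heterogeneity.csv", index=False, float_format="%.6f"
        )

    def run(self) -> Path:
        cfg_text = yaml.safe_dump(self.config, sort_keys=True)
        provenance = {
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "master_seed": self.master_seed,
        }
        (self.outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True)
        )
        (self.outdir / "config.yaml").write_text(cfg_text)
        for stage in (
            self.stage_data,
            self.stage_select_spec,
            self.stage_fit,
            self.stage_pool,
            self.stage_curves,
            self.stage_af,
            self.stage_heterogeneity,
        ):
            name = stage.__name__.removeprefix("stage_")
            try:
                stage()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
        return self.outdir


def run_study(config: dict, outdir) -> Path:
    """Execute the full pipeline; returns the output directory."""
    return StudyRunner(config, outdir).run()
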