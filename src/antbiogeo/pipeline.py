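"""End-to-end analysis pipeline: inventory -> rarefaction -> active species ->
turnover -> biogeography -> Markov assemblage dynamics.

The pipeline runs from a :class:`PipelineConfig` (YAML/JSON-loadable), writes
every numeric output as TSV/JSON under an output directory together with a run
manifest (config echo, seed, package version), and logs one structured line
per stage with counts in/out. When only an occurrence matrix is supplied
(matrix-only mode: the printed inventory tables), stages that need event
granularity report SKIPPED instead of failing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import asymptote, biogeography, markov, occurrence, rarefaction, synthetic, turnover
from .errors import AntbiogeoError, ConfigurationError

log = logging.getLogger("antbiogeo.pipeline")


@dataclass
class PipelineConfig:
    #: one of: events_path (event-level TSV), matrix_path (occurrence TSV),
    #: or simulate=True (synthetic park from `simulation`)
    events_path: str | None = None
    matrix_path: str | None = None
    simulate: bool = False
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.default_config)
    geography_path: str | None = None  # island geography TSV; packaged table if None

    n_iterations: int = 1000
    min_week_events: int = 5
    trim_fraction: float = 0.10
    coverage: float = 0.95
    alpha: float = 0.05
    cutoffs: tuple[float, float] = biogeography.DEFAULT_CUTOFFS
    asymptote_family: str = "exponential"
    dominants: tuple[str, ...] = markov.DEFAULT_DOMINANTS
    merge_rule: str = "standard"
    step_weeks: int = 2
    seed: int = 0
    out_dir: str = "antbiogeo-out"
    make_plots: bool = False
    drop_island: str | None = None  # sensitivity re-run with one island removed
    habitat: str | None = None      # restrict the Markov stage to one habitat

    def validate(self) -> None:
        sources = sum(bool(x) for x in (self.events_path, self.matrix_path, self.simulate))
        if sources != 1:
            raise ConfigurationError(
                "exactly one of events_path, matrix_path, simulate must be set"
            )
        if not 0 < self.coverage <= 1 or not 0 < self.alpha < 1:
            raise ConfigurationError("coverage in (0,1], alpha in (0,1) required")
        if not 0 <= self.trim_fraction < 0.5:
            raise ConfigurationError("trim_fraction must be in [0, 0.5)")
        if self.n_iterations < 1 or self.min_week_events < 1:
            raise ConfigurationError("n_iterations and min_week_events must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            sim = {k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                   if isinstance(v, list) else v for k, v in sim.items()}
            cfg.simulation = synthetic.SimulationConfig(**sim)
        return cfg


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_to_jsonable(v) for v in obj]
    return obj


class PipelineResult(dict):
    """Stage name -> status ('OK' | 'SKIPPED' | 'FAILED') plus artifacts."""

    @property
    def failed(self) -> bool:
        return any(v.get("status") == "FAILED" for v in self.values() if isinstance(v, dict))


def _write_tsv(df: pd.DataFrame, path: Path, units: str, stage: str) -> None:
    """Write a TSV with a comment header declaring units and producing stage."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# units: {units}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage the input supports; see module docstring."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    rng_root = np.random.SeedSequence(config.seed)

    def _seed(tag: str) -> int:
        # stable per-stage seeds derived from the run seed
        import zlib

        return (config.seed * 2654435761 + zlib.crc32(tag.encode())) % (2**31)

    # ---- stage: inventory -------------------------------------------------
    events = None
    truth = None
    try:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            events, truth = synthetic.simulate_park(sim_cfg)
            geos = tuple(
                occurrence.IslandGeo(n, a, i) for n, a, i in sim_cfg.islands
            )
        elif config.events_path:
            events = occurrence.load_events(config.events_path)
            geos = _load_geography(config.geography_path)
        else:
            geos = _load_geography(config.geography_path)

        if events is not None and config.drop_island:
            events = events.subset(lambda e: e.island != config.drop_island)
            geos = tuple(g for g in geos if g.island != config.drop_island)

        if events is not None:
            occ = occurrence.aggregate_occurrences(events, by="island")
        else:
            occ = occurrence.OccurrenceMatrix.from_tsv(config.matrix_path)
            if config.drop_island and config.drop_island in occ.groups:
                occ = occurrence.OccurrenceMatrix(
                    occ.data.drop(columns=[config.drop_island])
                )
                geos = tuple(g for g in geos if g.island != config.drop_island)
        _write_tsv(occ.data, out / "inventory" / "occurrence_matrix.tsv",
                   "occurrences (events containing the species)", "inventory")
        obs = occ.observed_species().to_frame("observed_species")
        obs.loc["total"] = len(occ.species)
        _write_tsv(obs, out / "inventory" / "observed_species.tsv", "species", "inventory")
        log.info("stage=inventory status=OK islands=%d species=%d total_occurrences=%d",
                 len(occ.groups), len(occ.species), occ.total)
        result["inventory"] = {
            "status": "OK", "occurrences": occ.total,
            "species": len(occ.species), "islands": len(occ.groups),
        }
    except AntbiogeoError as exc:
        log.error("stage=inventory status=FAILED error=%s", exc)
        (out / "FAILED").write_text(f"inventory: {exc}\n")
        result["inventory"] = {"status": "FAILED", "error": str(exc)}
        _write_manifest(config, out, result)
        return result

    matrix_only = events is None

    # ---- stage: rarefaction ----------------------------------------------
    if matrix_only:
        result["rarefaction"] = {"status": "SKIPPED", "reason": "matrix-only input"}
        log.info("stage=rarefaction status=SKIPPED reason=matrix-only")
    else:
        ens = rarefaction.rarefy(events, config.n_iterations, seed=_seed("rarefy"))
        curve = rarefaction.curve_summary(ens)
        _write_tsv(curve.to_frame().set_index("n_events"),
                   out / "rarefaction" / "curve_park.tsv",
                   "expected species (mean, 95% envelope)", "rarefaction")
        for isl, sub in events.by_island().items():
            c = rarefaction.curve_summary(
                rarefaction.rarefy(sub, config.n_iterations, seed=_seed(f"rarefy-{isl}"))
            )
            _write_tsv(c.to_frame().set_index("n_events"),
                       out / "rarefaction" / f"curve_{isl.replace(' ', '_')}.tsv",
                       "expected species (mean, 95% envelope)", "rarefaction")
        if config.make_plots:
            _plot_curves(events, config, out / "rarefaction" / "curves.png")
        log.info("stage=rarefaction status=OK iterations=%d", config.n_iterations)
        result["rarefaction"] = {"status": "OK", "park_s_obs": ens.s_obs}

    # ---- stage: active species -------------------------------------------
    summary_rows = []
    weekly_metrics = []  # per (island, week) rows for the ANCOVA
    if matrix_only:
        result["active_species"] = {"status": "SKIPPED", "reason": "matrix-only input"}
        log.info("stage=active_species status=SKIPPED reason=matrix-only")
    else:
        pools = {"total": events, **events.by_island()}
        for name, pool in pools.items():
            row = {"island": name, "s_obs_year": len(pool.species_pool),
                   "n_events": len(pool)}
            annual = asymptote.active_species(
                pool, "year", config.n_iterations, seed=_seed(f"as-{name}"),
                family=config.asymptote_family, trim_fraction=config.trim_fraction,
            )["year"]
            row["s_year_mean"], row["s_year_sd"] = annual.s_mean, annual.s_sd
            try:
                weekly = asymptote.active_species(
                    pool, "week", config.n_iterations, config.min_week_events,
                    seed=_seed(f"asw-{name}"), family=config.asymptote_family,
                    trim_fraction=config.trim_fraction,
                )
                mw, sw = asymptote.mean_weekly_estimate(weekly)
                row["s_week_mean"], row["s_week_sd"] = mw, sw
                for key, est in weekly.items():
                    weekly_metrics.append(
                        {"island": name, "week": int(key.split("-")[1]),
                         "s_week": est.s_mean, "s_obs_week": est.s_obs}
                    )
            except AntbiogeoError:
                row["s_week_mean"] = row["s_week_sd"] = np.nan
            c2 = rarefaction.chao2(pool)
            row["chao2"], row["chao2_se"] = c2.estimate, c2.se
            summary_rows.append(row)
        summary = pd.DataFrame(summary_rows).set_index("island")
        _write_tsv(summary, out / "active_species" / "summary.tsv",
                   "species (asymptotic estimates mean +/- SD)", "active_species")
        log.info("stage=active_species status=OK islands=%d", len(summary_rows) - 1)
        result["active_species"] = {"status": "OK", "summary": summary}

    # ---- stage: turnover ---------------------------------------------------
    if matrix_only:
        result["turnover"] = {"status": "SKIPPED", "reason": "matrix-only input"}
        log.info("stage=turnover status=SKIPPED reason=matrix-only")
    else:
        rows = []
        s_lookup = {r["island"]: r["s_year_mean"] for r in summary_rows}
        for name, pool in {"total": events, **events.by_island()}.items():
            rep = turnover.turnover_report(pool, s_estimate=s_lookup.get(name), scope=name)
            rows.append({
                "island": name, "alpha_mean": rep.alpha_mean, "alpha_sd": rep.alpha_sd,
                "turnover_space": rep.spatial_turnover,
                "turnover_time_mean": rep.temporal_turnover_mean,
                "turnover_time_sd": rep.temporal_turnover_sd,
                "s_pairing": "annual S / annual alpha",
            })
        tdf = pd.DataFrame(rows).set_index("island")
        _write_tsv(tdf, out / "turnover" / "turnover.tsv",
                   "species per event; ratios; Bray-Curtis in [0,1]", "turnover")
        log.info("stage=turnover status=OK islands=%d", len(rows) - 1)
        result["turnover"] = {"status": "OK", "table": tdf}

    # ---- stage: biogeography ----------------------------------------------
    try:
        classes = biogeography.classify_all(geos, config.cutoffs)
        _write_tsv(classes, out / "biogeography" / "island_classes.tsv",
                   "km^2, km, classes at cutoffs "
                   f"{config.cutoffs[0]} km / {config.cutoffs[1]} km^2", "biogeography")
        if matrix_only:
            # observed species stand in for estimates when only a matrix exists
            s_per_island = (occ.data > 0).sum(axis=0)
        else:
            s_per_island = summary.drop(index="total")["s_year_mean"]
        aligned = classes.join(s_per_island.rename("s"))
        reg_rows = []
        for pred in ("area_km2", "isolation_km"):
            try:
                r = biogeography.regress_metric(aligned["s"], aligned[pred])
                reg_rows.append({"predictor": pred, "slope": r.slope,
                                 "p": r.p_value, "adj_r2": r.adj_r2})
            except AntbiogeoError as exc:
                reg_rows.append({"predictor": pred, "error": str(exc)})
        _write_tsv(pd.DataFrame(reg_rows).set_index("predictor"),
                   out / "biogeography" / "regressions.tsv",
                   "OLS of island S on geography", "biogeography")
        anc_tables = {}
        if weekly_metrics:
            wdf = pd.DataFrame(weekly_metrics).join(
                classes[["distance_class", "size_class"]], on="island"
            )
            for cls_col in ("distance_class", "size_class"):
                try:
                    table = biogeography.ancova(
                        wdf, response="s_week", class_col=cls_col, week_col="week"
                    )
                    anc_tables[cls_col] = table
                    _write_tsv(table.terms, out / "biogeography" / f"ancova_{cls_col}.tsv",
                               "Type-I SS; F; p (response: weekly S)", "biogeography")
                except AntbiogeoError as exc:
                    log.warning("ancova %s failed: %s", cls_col, exc)
        log.info("stage=biogeography status=OK regressions=%d ancovas=%d",
                 len(reg_rows), len(anc_tables))
        result["biogeography"] = {
            "status": "OK", "classes": classes,
            "regressions": pd.DataFrame(reg_rows), "ancova": anc_tables,
        }
    except AntbiogeoError as exc:
        log.error("stage=biogeography status=FAILED error=%s", exc)
        (out / "FAILED").write_text(f"biogeography: {exc}\n")
        result["biogeography"] = {"status": "FAILED", "error": str(exc)}

    # ---- stage: markov -----------------------------------------------------
    if matrix_only:
        result["markov"] = {"status": "SKIPPED", "reason": "matrix-only input"}
        log.info("stage=markov status=SKIPPED reason=matrix-only")
    else:
        try:
            mk_events = events
            if config.habitat:
                mk_events = events.subset(lambda e: e.habitat == config.habitat)
            retained = markov.trim_rare(mk_events, config.coverage)
            series = [
                markov.fill_gaps(s)
                for s in markov.build_plot_series(mk_events, config.step_weeks, retained)
            ]
            classes = markov.merge_indistinguishable(
                series, alpha=config.alpha, merge_rule=config.merge_rule
            )
            tcm = markov.tabulate_transitions(series, classes)
            reduced = markov.reduce_states(tcm, alpha=config.alpha,
                                           merge_rule=config.merge_rule)
            p_red = markov.to_stochastic(reduced)
            pi_red = markov.stable_state(p_red, labels=reduced.labels)
            tcm4, p4, pi4 = markov.four_state_projection(series, config.dominants)
            _write_tsv(tcm.to_frame(), out / "markov" / "transitions_full.tsv",
                       "transition counts (multi-counting convention)", "markov")
            _write_tsv(reduced.to_frame(), out / "markov" / "transitions_reduced.tsv",
                       "transition counts after G-test state merging", "markov")
            _write_tsv(tcm4.to_frame(), out / "markov" / "transitions_4state.tsv",
                       "transition counts (3 dominants + other)", "markov")
            report = {
                "retained_species": sorted(retained),
                "n_states_enumerated": len({a for s in series for a in s.assemblages if a}),
                "n_states_merged": len(classes.species_sets),
                "n_states_reduced": len(reduced.labels),
                "reduced": {
                    "labels": reduced.labels,
                    "stochastic": p_red,
                    "stable_state": pi_red.pi,
                },
                "four_state": {
                    "labels": tcm4.labels,
                    "counts": tcm4.counts,
                    "mass_flux": tcm4.counts / max(tcm4.n_transitions, 1),
                    "stochastic": p4,
                    "stable_state": pi4.pi,
                },
            }
            (out / "markov" / "report.json").write_text(
                json.dumps(_to_jsonable(report), indent=2)
            )
            log.info(
                "stage=markov status=OK retained=%d states=%d reduced=%d transitions=%d",
                len(retained), report["n_states_merged"], len(reduced.labels),
                tcm.n_transitions,
            )
            result["markov"] = {"status": "OK", **report}
        except AntbiogeoError as exc:
            log.error("stage=markov status=FAILED error=%s", exc)
            (out / "FAILED").write_text(f"markov: {exc}\n")
            result["markov"] = {"status": "FAILED", "error": str(exc)}

    _write_manifest(config, out, result)
    return result


def _load_geography(path) -> tuple:
    if path is None:
        return occurrence.load_printed_fixtures().geography
    df = pd.read_csv(path, sep="\t")
    return tuple(
        occurrence.IslandGeo(r.island, float(r.area_km2), float(r.isolation_km))
        for r in df.itertuples(index=False)
    )


def _write_manifest(config: PipelineConfig, out: Path, result: PipelineResult) -> None:
    manifest = {
        "package": "antbiogeo",
        "version": _version,
        "seed": config.seed,
        "config": _to_jsonable(config),
        "stages": {k: v.get("status") for k, v in result.items() if isinstance(v, dict)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _plot_curves(events, config: PipelineConfig, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    for ax, grouper, title in (
        (axes[0], "method", "by sampling method"),
        (axes[1], "island", "by island"),
    ):
        groups = sorted({getattr(e, grouper) for e in events})
        for g in groups:
            sub = events.subset(lambda e, g=g: getattr(e, grouper) == g)
            if len(sub) < 2:
                continue
            c = rarefaction.curve_summary(
                rarefaction.rarefy(sub, min(config.n_iterations, 200), seed=config.seed)
            )
            ax.plot(c.n, c.mean, label=str(g))
            ax.fill_between(c.n, c.lower, c.upper, alpha=0.15)
        ax.set_xlabel("collecting events sampled")
        ax.set_title(title)
        ax.legend(fontsize=6)
    axes[0].set_ylabel("expected species")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
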