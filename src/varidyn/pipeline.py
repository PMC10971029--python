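"""End-to-end analysis: load, superpose, PCA, monitors, energies, FELs, tests.

``run_analysis`` consumes an :class:`AnalysisConfig` (usually from YAML),
executes every stage on every variant at the configured analysis
temperature, and emits one Table-style :class:`VariantReport` per non-WT
variant: PC-shift calls against the wild type, stronger/weaker interaction
calls per domain pair (backed by the down-sampling significance test),
an RMSD summary and distance-monitor summaries. Everything is deterministic
given the config, whose hash is recorded in the provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energetics, geometry, landscapes, modes, stats, superpose, structure_io
from .energetics import ParameterTable, SwitchingSpec
from .geometry import PairSpec
from .structure_io import Selection, Structure, TrajectoryEnsemble

__all__ = [
    "AnalysisConfig",
    "VariantInput",
    "TrajectorySource",
    "StatsParams",
    "VariantReport",
    "PipelineError",
    "run_analysis",
    "render_report",
]


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage and variant for diagnosis."""


@dataclass
class TrajectorySource:
    path: str
    replicate: int = 1
    temperature: float = 300.0


@dataclass
class VariantInput:
    name: str
    trajectories: list[TrajectorySource]
    parameters: str | None = None
    is_wt: bool = False


@dataclass
class StatsParams:
    m_per_draw: int = 100
    repetitions: int = 1000
    alpha: float = 1e-6
    seed: int = 0


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs, resolvable relative to ``base_dir``."""

    variants: list[VariantInput]
    reference: str
    base_dir: Path = field(default_factory=Path)
    fit_selection: str = "chain A and name CA"
    pca_selection: str = "chain B and name CA"
    domains: dict[str, str] = field(default_factory=dict)
    domain_pairs: list[tuple[str, str]] = field(default_factory=list)
    monitors: list[PairSpec] = field(default_factory=list)
    equilibration_fraction: float = 1.0 / 3.0
    pooling: str = "pooled"  # or "wt-only"
    n_modes: int = 3
    stats: StatsParams = field(default_factory=StatsParams)
    switching: SwitchingSpec = field(default_factory=SwitchingSpec)
    fel_pair: tuple[int, int] = (1, 2)
    fel_bins: int = 50
    temperature: float = 300.0
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        wt = [v for v in self.variants if v.is_wt]
        if len(wt) != 1:
            raise ValueError(f"exactly one variant must be flagged as WT, found {len(wt)}")
        if self.pooling not in ("pooled", "wt-only"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        for a, b in self.domain_pairs:
            for name in (a, b):
                if name not in self.domains:
                    raise ValueError(f"domain pair references undefined domain {name!r}")

    @property
    def wt(self) -> VariantInput:
        return next(v for v in self.variants if v.is_wt)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "AnalysisConfig":
        variants = [
            VariantInput(
                name=v["name"],
                is_wt=bool(v.get("wt", False)),
                parameters=v.get("parameters"),
                trajectories=[
                    TrajectorySource(
                        path=t["path"],
                        replicate=int(t.get("replicate", 1)),
                        temperature=float(t.get("temperature", 300.0)),
                    )
                    for t in v["trajectories"]
                ],
            )
            for v in raw["variants"]
        ]
        st = raw.get("stats", {})
        sw = raw.get("switching", {})
        fel = raw.get("fel", {})
        monitors = [
            PairSpec(
                chain_a=str(m["chain_a"]),
                residue_a=int(m["residue_a"]),
                chain_b=str(m["chain_b"]),
                residue_b=int(m["residue_b"]),
                atom_name=str(m.get("atom_name", "CA")),
            )
            for m in raw.get("monitors", [])
        ]
        return cls(
            variants=variants,
            reference=raw["reference"],
            base_dir=Path(base_dir),
            fit_selection=raw.get("fit_selection", "chain A and name CA"),
            pca_selection=raw.get("pca_selection", "chain B and name CA"),
            domains=dict(raw.get("domains", {})),
            domain_pairs=[tuple(p) for p in raw.get("domain_pairs", [])],
            monitors=monitors,
            equilibration_fraction=float(raw.get("equilibration_fraction", 1.0 / 3.0)),
            pooling=raw.get("pooling", "pooled"),
            n_modes=int(raw.get("n_modes", 3)),
            stats=StatsParams(
                m_per_draw=int(st.get("m_per_draw", 100)),
                repetitions=int(st.get("repetitions", 1000)),
                alpha=float(st.get("alpha", 1e-6)),
                seed=int(st.get("seed", 0)),
            ),
            switching=SwitchingSpec(
                r_on=float(sw.get("r_on", 10.0)),
                r_off=float(sw.get("r_off", 12.0)),
                dielectric=float(sw.get("dielectric", 1.0)),
            ),
            fel_pair=tuple(fel.get("pair", (1, 2))),
            fel_bins=int(fel.get("bins", 50)),
            temperature=float(raw.get("temperature", 300.0)),
            frame_interval=float(raw.get("frame_interval_ps", 2.0)),
        )

    def config_hash(self) -> str:
        def _default(o):
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return asdict(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class InteractionResult:
    """One domain pair's call for one variant."""

    pair_label: str
    call: str  # "+", "-", "n.s."
    variant_median: float
    wt_median: float
    median_t: float
    p_value: float


@dataclass
class VariantReport:
    """Table-style row for one variant."""

    name: str
    pc_calls: list[modes.PcShiftCall]
    interactions: list[InteractionResult]
    rmsd_median: float
    monitor_summaries: dict[str, dict[str, float]]
    provenance: dict

    def pc_call_string(self) -> str:
        hits = [c.call for c in self.pc_calls if c.call != "none"]
        return ",".join(hits) if hits else "none"


def _load_variant_ensembles(
    config: AnalysisConfig, variant: VariantInput, reference: Structure, fit_sel: Selection
) -> list[TrajectoryEnsemble]:
    out = []
    for src in variant.trajectories:
        if src.temperature != config.temperature:
            continue
        ens = structure_io.read_ensemble(
            config.base_dir / src.path,
            frame_interval=config.frame_interval,
            label=variant.name,
            replicate=src.replicate,
            temperature=src.temperature,
        )
        ens = structure_io.drop_equilibration(ens, config.equilibration_fraction)
        out.append(superpose.superpose_ensemble(ens, reference, fit_sel))
    if not out:
        raise PipelineError(
            f"variant {variant.name!r} has no trajectories at {config.temperature:g} K"
        )
    return out


def run_analysis(config: AnalysisConfig, out_dir: str | Path | None = None) -> list[VariantReport]:
    """Run every stage and return one report per non-WT variant.

    When ``out_dir`` is given, artifacts are written there: the report in
    TSV/JSON/markdown, per-variant projection and energy series, FEL grids
    and a provenance JSON.
    """
    try:
        reference = structure_io.read_structure(config.base_dir / config.reference)
    except Exception as err:
        raise PipelineError(f"stage load-reference: {err}") from err
    fit_sel = structure_io.resolve_selection(reference, config.fit_selection)
    pca_sel = structure_io.resolve_selection(reference, config.pca_selection)

    ensembles: dict[str, list[TrajectoryEnsemble]] = {}
    for variant in config.variants:
        try:
            ensembles[variant.name] = _load_variant_ensembles(config, variant, reference, fit_sel)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage load-superpose, variant {variant.name!r}: {err}") from err

    wt_name = config.wt.name
    try:
        pool = (
            [e for v in config.variants for e in ensembles[v.name]]
            if config.pooling == "pooled"
            else list(ensembles[wt_name])
        )
        basis = modes.fit_modes(pool, pca_sel, n_modes=config.n_modes)
        projections = {
            name: [modes.project(e, basis, pca_sel) for e in ens_list]
            for name, ens_list in ensembles.items()
        }
    except Exception as err:
        raise PipelineError(f"stage pca: {err}") from err

    params: dict[str, ParameterTable] = {}
    for variant in config.variants:
        if variant.parameters is not None:
            params[variant.name] = ParameterTable.from_tsv(config.base_dir / variant.parameters)

    energy_series: dict[str, dict[str, np.ndarray]] = {v.name: {} for v in config.variants}
    pair_labels = []
    for a, b in config.domain_pairs:
        label = f"{a}:{b}"
        pair_labels.append(label)
        sel_a = structure_io.resolve_selection(reference, config.domains[a])
        sel_b = structure_io.resolve_selection(reference, config.domains[b])
        for variant in config.variants:
            if variant.name not in params:
                continue
            try:
                series = [
                    energetics.interaction_energy_series(
                        e, sel_a, sel_b, params[variant.name], config.switching,
                        label_a=a, label_b=b,
                    ).values
                    for e in ensembles[variant.name]
                ]
            except Exception as err:
                raise PipelineError(
                    f"stage energetics ({label}), variant {variant.name!r}: {err}"
                ) from err
            energy_series[variant.name][label] = np.concatenate(series)

    fels = {}
    monitor_summaries: dict[str, dict[str, dict[str, float]]] = {}
    rmsd_medians: dict[str, float] = {}
    for variant in config.variants:
        name = variant.name
        try:
            rmsds = [
                superpose.rmsd_series(e, reference, pca_sel, fit_sel).values
                for e in ensembles[name]
            ]
            rmsd_medians[name] = float(np.median(np.concatenate(rmsds)))
            if config.monitors:
                pooled = {m.label: [] for m in config.monitors}
                for e in ensembles[name]:
                    for mon in geometry.distance_series(e, config.monitors):
                        pooled[mon.pair.label].append(mon.series)
                monitor_summaries[name] = {
                    lbl: geometry.summarize_monitor(
                        geometry.DistanceMonitor(pair=m, series=np.concatenate(pooled[m.label]))
                    )
                    for lbl, m in zip(pooled, config.monitors)
                }
            else:
                monitor_summaries[name] = {}
            if config.n_modes >= 2:
                fels[name] = landscapes.compute_fel(
                    projections[name], pc_pair=config.fel_pair, bins=config.fel_bins
                )
        except Exception as err:
            raise PipelineError(f"stage geometry/fel, variant {name!r}: {err}") from err

    provenance = {
        "config_hash": config.config_hash(),
        "stats_seed": config.stats.seed,
        "pooling": config.pooling,
        "temperature_K": config.temperature,
        "equilibration_fraction": config.equilibration_fraction,
        "n_modes": config.n_modes,
    }

    reports: list[VariantReport] = []
    for variant in config.variants:
        if variant.is_wt:
            continue
        name = variant.name
        pc_calls = [
            modes.call_pc_shift(projections[name], projections[wt_name], k)
            for k in range(1, config.n_modes + 1)
        ]
        interactions = []
        for label in pair_labels:
            if label not in energy_series[name] or label not in energy_series[wt_name]:
                continue
            v_series = energy_series[name][label]
            w_series = energy_series[wt_name][label]
            try:
                test = stats.downsample_test(
                    v_series,
                    w_series,
                    m_per_draw=config.stats.m_per_draw,
                    repetitions=config.stats.repetitions,
                    seed=config.stats.seed,
                    alpha=config.stats.alpha,
                )
            except Exception as err:
                raise PipelineError(f"stage stats ({label}), variant {name!r}: {err}") from err
            interactions.append(
                InteractionResult(
                    pair_label=label,
                    call=energetics.interaction_call(v_series, w_series, test),
                    variant_median=float(np.median(v_series)),
                    wt_median=float(np.median(w_series)),
                    median_t=test.median_t,
                    p_value=test.p_value,
                )
            )
        reports.append(
            VariantReport(
                name=name,
                pc_calls=pc_calls,
                interactions=interactions,
                rmsd_median=rmsd_medians[name],
                monitor_summaries=monitor_summaries[name],
                provenance=provenance,
            )
        )

    if out_dir is not None:
        _write_artifacts(Path(out_dir), config, reports, projections, energy_series, fels, provenance)
    return reports


def _write_artifacts(out_dir, config, reports, projections, energy_series, fels, provenance) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for fmt in ("tsv", "json", "markdown"):
        suffix = {"tsv": "tsv", "json": "json", "markdown": "md"}[fmt]
        render_report(reports, format=fmt, path=out_dir / f"report.{suffix}")
    for name, projs in projections.items():
        frames = [
            pd.DataFrame(
                p.scores, columns=[f"PC{k + 1}" for k in range(p.scores.shape[1])]
            ).assign(replicate=p.replicate)
            for p in projs
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / f"projections_{name}.tsv", sep="\t", index=False
        )
    for name, by_pair in energy_series.items():
        if by_pair:
            pd.DataFrame(by_pair).to_csv(out_dir / f"energies_{name}.tsv", sep="\t", index=False)
    for name, grid in fels.items():
        grid.to_tsv(out_dir / f"fel_{name}.tsv", out_dir / f"fel_{name}.meta.json")
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))


def _report_table(reports: list[VariantReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row: dict = {"variant": r.name, "delta_PCs": r.pc_call_string()}
        for c in r.pc_calls:
            row[f"PC{c.pc_index}_shift_A"] = round(c.shift, 4)
            row[f"PC{c.pc_index}_wt_sd_A"] = round(c.wt_sd, 4)
        for it in r.interactions:
            row[f"{it.pair_label}_call"] = it.call
            row[f"{it.pair_label}_dE_kcal_mol"] = round(it.variant_median - it.wt_median, 4)
            row[f"{it.pair_label}_median_t"] = round(it.median_t, 4)
            row[f"{it.pair_label}_p"] = float(f"{it.p_value:.3e}")
        row["rmsd_median_A"] = round(r.rmsd_median, 4)
        for lbl, summ in r.monitor_summaries.items():
            row[f"dist_{lbl}_median_A"] = round(summ["median"], 4)
        rows.append(row)
    return pd.DataFrame(rows)


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_report(
    reports: list[VariantReport], format: str = "tsv", path: str | Path | None = None
) -> str:
    """Render reports as TSV, JSON or markdown; returns the text.

    One row per variant; not-significant interaction calls are rendered
    exactly as ``n.s.``; significant calls carry their p-value so an
    asterisk-style significance convention can be applied downstream.
    """
    if not reports:
        raise ValueError("no reports to render")
    df = _report_table(reports)
    if format == "tsv":
        text = df.to_csv(sep="\t", index=False)
    elif format == "json":
        payload = []
        for r in reports:
            payload.append(
                {
                    "variant": r.name,
                    "pc_calls": [asdict(c) for c in r.pc_calls],
                    "interactions": [asdict(i) for i in r.interactions],
                    "rmsd_median_A": r.rmsd_median,
                    "monitors": r.monitor_summaries,
                    "provenance": r.provenance,
                }
            )
        text = json.dumps(payload, indent=2, sort_keys=True)
    elif format == "markdown":
        text = _markdown_table(df)
    else:
        raise ValueError(f"unknown report format {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
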