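"""End-to-end study orchestration: corpora -> networks -> panel -> fits ->
baselines -> statistical battery -> reports.

All outputs are plain text (TSV + JSON + Pajek ``.net``); a manifest
records the configuration hash, package version and every seed so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

import synnet
from synnet.baselines import assess_small_world, ensemble_metrics
from synnet.distribution import (
    compare_models,
    cumulative_degree_distribution,
    fit_poisson,
    fit_power_law,
    fit_report,
)
from synnet.errors import SynnetError, ValidationError
from synnet.metrics import LMode, MetricsRow, NCForm, compute_metrics_row, degree_stats
from synnet.network import build_network
from synnet.stats import TTestVariant, run_battery
from synnet.treebank import (
    CorpusMeta,
    Treebank,
    read_conllu,
    read_dependency_table,
    write_pajek,
)

#: display headers used in the TSV mirror of the metrics panel
PANEL_DISPLAY = {
    "gamma_prime": "γ′",
    "fit_R2": "R²",
    "k_mean": "⟨k⟩",
    "token_count": "tokens",
}
PANEL_DISPLAY_INVERSE = {v: k for k, v in PANEL_DISPLAY.items()}


@dataclass(frozen=True)
class CorpusEntry:
    path: str
    format: Literal["table", "conllu"]
    label: str
    modality: str
    level: int | str


@dataclass
class StudyConfig:
    corpora: list[CorpusEntry]
    out_dir: str = "study_out"
    l_mode: LMode = "reachable"
    nc_form: NCForm = "exact"
    punct_tags: Sequence[str] = ("wp", "PU", "PUNCT")
    k_min: int = 1
    baseline_reps: int = 10
    baseline_seed: int = 0
    tau_c: float = 5.0
    tau_l: float = 1.2
    ttest_plan: dict[str, TTestVariant] = field(default_factory=dict)
    run_battery: bool = True

    def __post_init__(self) -> None:
        if not self.corpora:
            raise ValidationError("study config needs at least one corpus")
        labels = [c.label for c in self.corpora]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"corpus labels are not unique: {labels}")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        corpora = [CorpusEntry(**c) for c in raw.pop("corpora")]
        level_fixed = [
            dataclasses.replace(c, level=_coerce_level(c.level)) for c in corpora
        ]
        return cls(corpora=level_fixed, **raw)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["punct_tags"] = list(self.punct_tags)
        return d


def _coerce_level(level):
    if isinstance(level, str) and level.isdigit():
        return int(level)
    return level


def _read_corpus(entry: CorpusEntry, punct_tags) -> Treebank:
    meta = CorpusMeta(modality=entry.modality, level=entry.level, label=entry.label)
    if entry.format == "table":
        return read_dependency_table(entry.path, punct_tags=punct_tags, meta=meta)
    if entry.format == "conllu":
        return read_conllu(entry.path, punct_tags=punct_tags, meta=meta)
    raise ValidationError(f"unknown corpus format {entry.format!r}")


def panel_to_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write the metrics panel with its display headers."""
    out = table.rename(columns=PANEL_DISPLAY)
    out.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a metrics panel TSV/JSON, mapping display headers back."""
    path = Path(path)
    if path.suffix == ".json":
        table = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    else:
        table = pd.read_csv(path, sep="\t")
    return table.rename(columns=PANEL_DISPLAY_INVERSE)


def run_pipeline(config: StudyConfig) -> dict:
    """Run every stage for every corpus and write all reports.

    Returns the study report dict (also written to ``report.json``). Any
    stage failure aborts with the stage and corpus label in the message,
    and removes files already written for this run.
    """
    out_dir = Path(config.out_dir)
    net_dir = out_dir / "networks"
    created: list[Path] = []
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        net_dir.mkdir(exist_ok=True)
        rows: list[MetricsRow] = []
        fits: dict[str, dict] = {}
        baselines: dict[str, dict] = {}
        for entry in config.corpora:
            stage = "read"
            try:
                tb = _read_corpus(entry, config.punct_tags)
                stage = "build"
                net = build_network(tb)
                pajek_path = net_dir / f"{entry.label}.net"
                write_pajek(net, pajek_path)
                created.append(pajek_path)
                stage = "fitdist"
                dist = cumulative_degree_distribution(degree_stats(net))
                power = fit_power_law(dist, k_min=config.k_min)
                pois = fit_poisson(dist, k_min=config.k_min)
                comparison = compare_models(power, pois)
                fits[entry.label] = fit_report(comparison)
                stage = "metrics"
                row = compute_metrics_row(
                    net,
                    tb.meta,
                    fit=power,
                    token_count=tb.token_count,
                    l_mode=config.l_mode,
                    nc_form=config.nc_form,
                )
                rows.append(row)
                stage = "baseline"
                ens = ensemble_metrics(
                    net.N,
                    net.M,
                    reps=config.baseline_reps,
                    seed=config.baseline_seed,
                )
                sw = assess_small_world(row, ens, config.tau_c, config.tau_l)
                baselines[entry.label] = {
                    "ensemble": dataclasses.asdict(ens),
                    "assessment": dataclasses.asdict(sw),
                }
            except SynnetError as exc:
                raise SynnetError(
                    f"stage {stage!r} failed for corpus {entry.label!r}: {exc}"
                ) from exc

        table = pd.DataFrame([r.to_dict() for r in rows])
        metrics_tsv = out_dir / "metrics.tsv"
        metrics_json = out_dir / "metrics.json"
        panel_to_tsv(table, metrics_tsv)
        metrics_json.write_text(
            table.to_json(orient="records", indent=2), encoding="utf-8"
        )
        created.extend([metrics_tsv, metrics_json])

        battery = None
        if config.run_battery:
            battery = run_battery(table, ttest_plan=config.ttest_plan)
            battery_json = out_dir / "battery.json"
            battery_json.write_text(json.dumps(battery, indent=2), encoding="utf-8")
            created.append(battery_json)

        report = {
            "metrics": table.to_dict(orient="records"),
            "fits": fits,
            "baselines": baselines,
            "battery": battery,
        }
        config_dict = config.to_json_dict()
        manifest = {
            "synnet_version": synnet.__version__,
            "config": config_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(config_dict, sort_keys=True).encode()
            ).hexdigest(),
            "baseline_seed": config.baseline_seed,
        }
        for name, payload in (
            ("fits.json", fits),
            ("baselines.json", baselines),
            ("report.json", report),
            ("manifest.json", manifest),
        ):
            p = out_dir / name
            p.write_text(json.dumps(payload, indent=2), encoding="utf-8")
            created.append(p)
        return report
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
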