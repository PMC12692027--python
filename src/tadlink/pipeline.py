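"""End-to-end orchestration: consensus → TAD assignment → pairing →
quantification → correlation (+ adjacent null) → cross-tissue stable pairs.

One YAML config drives the run. A *tissue* is one pair of DE tables
(promoters + enhancers); a multi-tissue study is configuration, not a
separate code path. All intermediate artifacts are TSV/BED in the output
directory; nothing written contains timestamps, so identical (config, seed)
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import ConsensusReport, TadSet, build_consensus, consensus_report
from .correlation import (
    AssociationReport,
    adjacent_tad_null,
    aggregate_by_tad,
    aggregates_to_frame,
    association_battery,
    format_p,
)
from .intervals import IntervalSet, assign_to_tads, read_bed, write_bed
from .pairing import (
    DEFAULT_FDR,
    DEFAULT_MAX_DISTANCE,
    EPPair,
    filter_differential,
    load_de_table,
    pairs_by_tad,
    pairs_to_frame,
    stable_pairs,
)
from .quantify import TissueInteractionProfile, profile_from_pairs

logger = logging.getLogger("tadlink")

__all__ = ["ConfigError", "PipelineError", "RunConfig", "TissueInputs", "validate_config", "run_pipeline", "RunReport"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the offending input."""


@dataclass
class TissueInputs:
    name: str
    de_prom: Path
    de_enh: Path


@dataclass
class RunConfig:
    promoters: Path
    enhancers: Path
    prom_counts: Path
    enh_counts: Path
    tissues: list[TissueInputs]
    outdir: Path
    tads: Path | None = None
    tads_a: Path | None = None
    tads_b: Path | None = None
    consensus_mode: str = "intersect"
    fdr: float = DEFAULT_FDR
    max_distance: int = DEFAULT_MAX_DISTANCE
    pseudocount: float = 1.0
    adjacent_null: bool = True
    seed: int = 0


@dataclass
class RunReport:
    consensus: ConsensusReport | None
    profiles: dict[str, TissueInteractionProfile]
    associations: dict[str, dict[str, AssociationReport | None]]
    stable: list[tuple[tuple[str, str], dict[str, str | None]]] | None
    provenance: dict[str, str | int]


_REQUIRED_KEYS = ("promoters", "enhancers", "prom_counts", "enh_counts", "tissues", "outdir")
_KNOWN_KEYS = set(_REQUIRED_KEYS) | {
    "tads",
    "tads_a",
    "tads_b",
    "consensus_mode",
    "fdr",
    "max_distance",
    "pseudocount",
    "adjacent_null",
    "seed",
}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, applying defaults.

    Unknown keys warn; missing required keys, bad ranges, or nonexistent
    input paths raise :class:`ConfigError` with every problem listed.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")

    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            logger.warning("config: unknown key %r ignored", key)
    for key in _REQUIRED_KEYS:
        if key not in raw:
            errors.append(f"missing required key: {key}")
    has_single = "tads" in raw
    has_pair = "tads_a" in raw and "tads_b" in raw
    if not has_single and not has_pair:
        errors.append("need either 'tads' or both 'tads_a' and 'tads_b'")

    fdr = float(raw.get("fdr", DEFAULT_FDR))
    if not 0 < fdr <= 1:
        errors.append(f"fdr out of range (0,1]: {fdr}")
    max_distance = int(raw.get("max_distance", DEFAULT_MAX_DISTANCE))
    if max_distance <= 0:
        errors.append(f"max_distance must be positive: {max_distance}")
    pseudocount = float(raw.get("pseudocount", 1.0))
    if pseudocount <= 0:
        errors.append(f"pseudocount must be positive: {pseudocount}")
    mode = raw.get("consensus_mode", "intersect")
    if mode not in ("intersect", "merge_chained"):
        errors.append(f"unknown consensus_mode: {mode!r}")

    tissues: list[TissueInputs] = []
    raw_tissues = raw.get("tissues", {})
    if not isinstance(raw_tissues, dict) or (not raw_tissues and "tissues" in raw):
        errors.append("tissues must be a non-empty mapping of name -> {de_prom, de_enh}")
    else:
        for name, entry in raw_tissues.items():
            if not isinstance(entry, dict) or "de_prom" not in entry or "de_enh" not in entry:
                errors.append(f"tissue {name!r} must define de_prom and de_enh")
            else:
                tissues.append(TissueInputs(name, Path(entry["de_prom"]), Path(entry["de_enh"])))

    base = path.parent

    def _resolve(key: str) -> Path | None:
        if key not in raw or raw[key] is None:
            return None
        p = Path(raw[key])
        return p if p.is_absolute() else base / p

    cfg = RunConfig(
        promoters=_resolve("promoters") or Path("missing"),
        enhancers=_resolve("enhancers") or Path("missing"),
        prom_counts=_resolve("prom_counts") or Path("missing"),
        enh_counts=_resolve("enh_counts") or Path("missing"),
        tissues=[
            TissueInputs(
                t.name,
                t.de_prom if t.de_prom.is_absolute() else base / t.de_prom,
                t.de_enh if t.de_enh.is_absolute() else base / t.de_enh,
            )
            for t in tissues
        ],
        outdir=_resolve("outdir") or Path("missing"),
        tads=_resolve("tads"),
        tads_a=_resolve("tads_a"),
        tads_b=_resolve("tads_b"),
        consensus_mode=mode,
        fdr=fdr,
        max_distance=max_distance,
        pseudocount=pseudocount,
        adjacent_null=bool(raw.get("adjacent_null", True)),
        seed=int(raw.get("seed", 0)),
    )
    if not errors:
        for label, p in [
            ("promoters", cfg.promoters),
            ("enhancers", cfg.enhancers),
            ("prom_counts", cfg.prom_counts),
            ("enh_counts", cfg.enh_counts),
            *[(f"tads({x})", getattr(cfg, x)) for x in ("tads", "tads_a", "tads_b") if getattr(cfg, x)],
            *[(f"tissue {t.name} de_prom", t.de_prom) for t in cfg.tissues],
            *[(f"tissue {t.name} de_enh", t.de_enh) for t in cfg.tissues],
        ]:
            if not Path(p).exists():
                errors.append(f"{label}: path does not exist: {p}")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items() if k != "tissues"}
        | {"tissues": [(t.name, str(t.de_prom), str(t.de_enh)) for t in config.tissues]},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_counts(path: Path) -> pd.Series:
    """Feature x sample TSV -> per-feature total counts across samples."""
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: counts table needs a feature_id column")
    df = df.set_index("feature_id")
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: counts table has no sample columns")
    return df.sum(axis=1)


def _stage(name: str):
    """Decorator-free stage guard: re-raise any failure naming the stage."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _write_association_tsv(path: Path, rows: list[tuple[str, AssociationReport | None]]) -> None:
    cols = [
        "pairing",
        "n_tads",
        "pearson_r",
        "pearson_p",
        "spearman_rho",
        "spearman_p",
        "kendall_tau",
        "kendall_p",
        "slr_slope",
        "slr_intercept",
        "theilsen_slope",
        "theilsen_intercept",
    ]
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for label, rep in rows:
            if rep is None:
                continue
            d = rep.to_dict()
            fh.write(
                "\t".join(
                    [
                        label,
                        str(d["n_tads"]),
                        *(format(d[c], ".6g") for c in ("pearson_r",)),
                        format_p(d["pearson_p"]),
                        format(d["spearman_rho"], ".6g"),
                        format_p(d["spearman_p"]),
                        format(d["kendall_tau"], ".6g"),
                        format_p(d["kendall_p"]),
                        format(d["slr_slope"], ".6g"),
                        format(d["slr_intercept"], ".6g"),
                        format(d["theilsen_slope"], ".6g"),
                        format(d["theilsen_intercept"], ".6g"),
                    ]
                )
                + "\n"
            )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; deterministic given inputs and seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cons_report: ConsensusReport | None = None
    with _stage("consensus"):
        if config.tads_a and config.tads_b:
            a = TadSet.from_bed(config.tads_a)
            b = TadSet.from_bed(config.tads_b)
            tads = build_consensus(a, b, mode=config.consensus_mode)
            cons_report = consensus_report(a, b, mode=config.consensus_mode)
            write_bed(tads.intervals, outdir / "consensus_tads.bed")
            pd.DataFrame([vars(cons_report)]).to_csv(
                outdir / "consensus_report.tsv", sep="\t", index=False
            )
        else:
            tads = TadSet.from_bed(config.tads)

    with _stage("load_features"):
        promoters = read_bed(config.promoters)
        enhancers = read_bed(config.enhancers)
        prom_totals = _read_counts(config.prom_counts)
        enh_totals = _read_counts(config.enh_counts)

    with _stage("assign_to_tads"):
        prom_assign = assign_to_tads(promoters, tads)
        enh_assign = assign_to_tads(enhancers, tads)
        logger.info(
            "assigned %d/%d promoters, %d/%d enhancers to TADs",
            len(prom_assign), len(promoters), len(enh_assign), len(enhancers),
        )

    with _stage("pair_enumeration"):
        tad_pairs = pairs_by_tad(promoters, enhancers, tads)
        logger.info("same-TAD candidate pairs: %d", len(tad_pairs))

    profiles: dict[str, TissueInteractionProfile] = {}
    associations: dict[str, dict[str, AssociationReport | None]] = {}
    per_tissue_filtered: dict[str, list[EPPair]] = {}

    for tissue in config.tissues:
        with _stage(f"tissue:{tissue.name}:filter"):
            de_prom = load_de_table(tissue.de_prom)
            de_enh = load_de_table(tissue.de_enh)
            kept = filter_differential(tad_pairs, de_prom, de_enh, fdr_threshold=config.fdr)
            per_tissue_filtered[tissue.name] = kept
            pairs_to_frame(kept).to_csv(
                outdir / f"pairs_{tissue.name}.tsv", sep="\t", index=False
            )
            logger.info("tissue %s: %d -> %d pairs after DE filter", tissue.name, len(tad_pairs), len(kept))

        with _stage(f"tissue:{tissue.name}:quantify"):
            profile = profile_from_pairs(kept, tissue.name)
            profiles[tissue.name] = profile
            pd.DataFrame(
                [
                    {
                        "tissue": profile.tissue,
                        "total": profile.total,
                        "n_pp": profile.n_pp,
                        "n_pm": profile.n_pm,
                        "n_mp": profile.n_mp,
                        "n_mm": profile.n_mm,
                        "p_pp": profile.p_pp,
                        "p_pm": profile.p_pm,
                        "p_mp": profile.p_mp,
                        "p_mm": profile.p_mm,
                    }
                ]
            ).to_csv(outdir / f"profile_{tissue.name}.tsv", sep="\t", index=False)

        with _stage(f"tissue:{tissue.name}:correlate"):
            agg = aggregate_by_tad(
                prom_totals, enh_totals, prom_assign, enh_assign, pseudocount=config.pseudocount
            )
            same = association_battery(agg)
            adjacent: AssociationReport | None = None
            if config.adjacent_null:
                adjacent = adjacent_tad_null(agg, tads.ids_in_order())
            associations[tissue.name] = {"same_tad": same, "adjacent": adjacent}
            aggregates_to_frame(agg).to_csv(
                outdir / f"scatter_{tissue.name}.tsv", sep="\t", index=False
            )
            _write_association_tsv(
                outdir / f"correlation_{tissue.name}.tsv",
                [("same_tad", same), ("adjacent_null", adjacent)],
            )

    stable = None
    if len(per_tissue_filtered) >= 2:
        with _stage("stable_pairs"):
            stable = stable_pairs(per_tissue_filtered)
            rows = [
                {"promoter_id": k[0], "enhancer_id": k[1], **{f"pattern_{t}": pat for t, pat in pats.items()}}
                for k, pats in stable
            ]
            pd.DataFrame(rows).to_csv(outdir / "stable_pairs.tsv", sep="\t", index=False)
            logger.info("stable pairs across %d tissues: %d", len(per_tissue_filtered), len(stable))

    provenance = {"tadlink_version": __version__, "config_hash": _config_hash(config), "seed": config.seed}
    report = RunReport(cons_report, profiles, associations, stable, provenance)

    with _stage("report"):
        payload = {
            "provenance": provenance,
            "consensus": vars(cons_report) if cons_report else None,
            "profiles": {t: vars(p) for t, p in profiles.items()},
            "associations": {
                t: {k: (r.to_dict() if r else None) for k, r in d.items()}
                for t, d in associations.items()
            },
            "n_stable_pairs": len(stable) if stable is not None else None,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    return report
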