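"""Readers/writers for the TSV exchange formats, the JSON report, and the pipeline.

Canonical formats (UTF-8, tab-separated):

* founder table — first column ``marker``, one column per founder; a cell
  holds one or more integer fragment lengths separated by commas, hyphens or
  en-dashes (published tables use en-dashes for co-amplified fragments);
* phased haplotype table — ``haplotype_id`` then one integer column per
  marker, ``NA`` for missing;
* genotype table — ``sample_id`` then one ``a/b`` column per marker with
  ``NA`` for a missing allele;
* spectrum table — columns ``k`` and ``n_k``.

Marker columns are aligned to the panel by header name, never by position.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import ne_grid
from .haplotypes import (
    FounderSet,
    GenotypeRecord,
    HaplotypeObservation,
    MarkerPanel,
    RecombinationCountVector,
    classify_population,
)
from .poisson import PoissonFit, RateEstimate, gof_test, rate_estimate

__all__ = [
    "read_founder_table",
    "write_founder_table",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_spectrum_table",
    "write_spectrum_table",
    "load_mauritius_founders",
    "load_mauritius_spectrum",
    "AnalysisConfig",
    "Report",
    "run_pipeline",
]

log = logging.getLogger("mhcrec")

_ALLELE_SEP = re.compile(r"[,−–-]")


def _parse_allele_cell(cell: str, where: str) -> frozenset[int]:
    parts = [p for p in _ALLELE_SEP.split(str(cell).strip()) if p]
    if not parts:
        raise ValueError(f"{where}: empty allele cell")
    try:
        alleles = frozenset(int(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"{where}: non-integer allele in {cell!r}") from exc
    return alleles


def read_founder_table(path: str | Path) -> tuple[MarkerPanel, FounderSet]:
    """Read a founder table; row order defines the marker panel order."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "marker":
        raise ValueError(f"{path}: first column must be 'marker'")
    markers = list(frame["marker"])
    if len(set(markers)) != len(markers):
        dup = [m for m in markers if markers.count(m) > 1]
        raise ValueError(f"{path}: duplicate marker(s) {sorted(set(dup))}")
    founder_names = tuple(frame.columns[1:])
    if not founder_names:
        raise ValueError(f"{path}: no founder columns")
    alleles: dict[str, dict[str, frozenset[int]]] = {f: {} for f in founder_names}
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        marker = row[0]
        for j, f in enumerate(founder_names, start=1):
            cell = row[j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(f"{path} line {line_no}: empty cell for {f}")
            alleles[f][marker] = _parse_allele_cell(cell, f"{path} line {line_no}")
    panel = MarkerPanel(markers=tuple(markers))
    return panel, FounderSet(founders=founder_names, alleles=alleles)


def write_founder_table(
    path: str | Path, panel: MarkerPanel, founders: FounderSet
) -> None:
    rows = []
    for m in panel.markers:
        row: dict[str, str] = {"marker": m}
        for f in founders.founders:
            row[f] = ",".join(str(a) for a in sorted(founders.allele_set(f, m)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _aligned_marker_columns(frame: pd.DataFrame, panel: MarkerPanel, path) -> list[str]:
    cols = list(frame.columns[1:])
    unknown = set(cols) - set(panel.markers)
    if unknown:
        raise ValueError(f"{path}: unknown marker(s) in header: {sorted(unknown)}")
    missing = set(panel.markers) - set(cols)
    if missing:
        raise ValueError(f"{path}: panel marker(s) absent: {sorted(missing)}")
    return list(panel.markers)


def read_haplotype_table(
    path: str | Path, panel: MarkerPanel
) -> dict[str, HaplotypeObservation]:
    """Phased haplotypes keyed by id, aligned to the panel by header names."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    order = _aligned_marker_columns(frame, panel, path)
    out: dict[str, HaplotypeObservation] = {}
    id_col = frame.columns[0]
    for _, row in frame.iterrows():
        alleles: list[int | None] = []
        for m in order:
            v = row[m]
            alleles.append(None if pd.isna(v) or v == "NA" else int(v))
        out[str(row[id_col])] = HaplotypeObservation(tuple(alleles))
    return out


def write_haplotype_table(
    path: str | Path,
    panel: MarkerPanel,
    haplotypes: dict[str, HaplotypeObservation],
) -> None:
    rows = []
    for hid, hap in haplotypes.items():
        row: dict[str, Any] = {"haplotype_id": hid}
        for m, a in zip(panel.markers, hap.alleles):
            row[m] = "NA" if a is None else a
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_table(
    path: str | Path, panel: MarkerPanel
) -> list[GenotypeRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    order = _aligned_marker_columns(frame, panel, path)
    id_col = frame.columns[0]
    records = []
    for _, row in frame.iterrows():
        pairs: list[tuple[int | None, int | None]] = []
        for m in order:
            cell = row[m]
            if pd.isna(cell) or cell == "NA":
                pairs.append((None, None))
                continue
            halves = str(cell).split("/")
            if len(halves) != 2:
                raise ValueError(f"{path}: malformed genotype cell {cell!r}")
            pairs.append(
                tuple(None if h == "NA" else int(h) for h in halves)  # type: ignore[arg-type]
            )
        records.append(GenotypeRecord(sample_id=str(row[id_col]), pairs=tuple(pairs)))
    return records


def write_genotype_table(
    path: str | Path, panel: MarkerPanel, records: Sequence[GenotypeRecord]
) -> None:
    rows = []
    for rec in records:
        row: dict[str, Any] = {"sample_id": rec.sample_id}
        for m, (a, b) in zip(panel.markers, rec.pairs):
            row[m] = f"{'NA' if a is None else a}/{'NA' if b is None else b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spectrum_table(path: str | Path) -> RecombinationCountVector:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != ["k", "n_k"]:
        raise ValueError(f"{path}: spectrum table needs columns 'k' and 'n_k'")
    if list(frame["k"]) != list(range(len(frame))):
        raise ValueError(f"{path}: k must run 0,1,2,... without gaps")
    return RecombinationCountVector(tuple(int(v) for v in frame["n_k"]))


def write_spectrum_table(path: str | Path, spectrum: RecombinationCountVector) -> None:
    pd.DataFrame(
        {"k": range(len(spectrum.counts)), "n_k": spectrum.counts}
    ).to_csv(path, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("mhcrec.data") / name)


def load_mauritius_founders() -> tuple[MarkerPanel, FounderSet]:
    """The packaged 17-marker, 7-founder haplotype table of the Mauritian macaque MHC."""
    return read_founder_table(_data_path("mauritius_founders.tsv"))


def load_mauritius_spectrum() -> RecombinationCountVector:
    """The packaged observed recombination spectrum (1500 haplotypes)."""
    return read_spectrum_table(_data_path("mauritius_spectrum.tsv"))


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    founders_path: str | None = None  # None = packaged Mauritian table
    haplotypes_path: str | None = None  # phased haplotype TSV
    spectrum_path: str | None = None  # or inject the spectrum directly
    alpha: float = 0.05
    min_expected: float = 5.0
    elapsed_years: float = 400.0
    generation_times: tuple[float, ...] = (4.0, 8.0)
    heterozygote_frequency: float = 0.90
    orphan_policy: str = "mutation"
    k: float = 12000.0
    n0_grid: tuple[float, ...] = (12.0, 90.0)
    r0_grid: tuple[float, ...] = (0.1, 0.4)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("generation_times", "n0_grid", "r0_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class Report:
    """Everything the analysis prints, JSON-serialisable and round-trippable."""

    spectrum: tuple[int, ...]
    n: int
    lambda_hat: float
    ci_low: float
    ci_high: float
    alpha: float
    gof_statistic: float
    gof_df: int
    gof_p: float
    gof_bins: tuple[dict[str, Any], ...]
    rates: tuple[dict[str, float], ...]
    ne_table: tuple[dict[str, float], ...]
    ne_min: float
    ne_max: float
    version: str
    config: dict[str, Any]

    def to_json(self, indent: int | None = 2) -> str:
        payload = dataclasses.asdict(self)
        payload["display"] = {
            "lambda_hat": round(self.lambda_hat, 3),
            "ci": [round(self.ci_low, 3), round(self.ci_high, 3)],
            "chi2": round(self.gof_statistic, 3),
            "p": round(self.gof_p, 3),
            "expected": [
                round(b["expected"], 2) for b in self.gof_bins
            ],
            "rates": [
                {k: round(v, 4) for k, v in r.items()} for r in self.rates
            ],
            "ne_range": [round(self.ne_min), round(self.ne_max)],
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        raw = json.loads(text)
        raw.pop("display", None)
        raw["spectrum"] = tuple(raw["spectrum"])
        raw["gof_bins"] = tuple(raw["gof_bins"])
        raw["rates"] = tuple(raw["rates"])
        raw["ne_table"] = tuple(raw["ne_table"])
        return cls(**raw)


def run_pipeline(config: AnalysisConfig) -> Report:
    """classify → fit → CI → goodness of fit → rates → Ne grid.

    The spectrum comes from a phased-haplotype table run through the mosaic
    classifier, or directly from a spectrum table when classification has
    already been done elsewhere.
    """
    if config.founders_path:
        panel, founders = read_founder_table(config.founders_path)
    else:
        panel, founders = load_mauritius_founders()
    log.info("panel: %d markers, %d founders", len(panel), len(founders.founders))

    if config.haplotypes_path:
        haps = read_haplotype_table(config.haplotypes_path, panel)
        log.info("classifying %d phased haplotypes", len(haps))
        cls = classify_population(
            panel, founders, haps.values(), policy=config.orphan_policy
        )
        spectrum = cls.spectrum
    elif config.spectrum_path:
        spectrum = read_spectrum_table(config.spectrum_path)
    else:
        raise ValueError("config must provide haplotypes_path or spectrum_path")
    log.info("spectrum: %s (n = %d)", spectrum.counts, spectrum.n)

    fit = PoissonFit.from_spectrum(spectrum, alpha=config.alpha)
    log.info(
        "lambda_hat = %.4f, %d%% CI (%.4f, %.4f)",
        fit.lambda_hat,
        round(100 * (1 - config.alpha)),
        fit.ci_low,
        fit.ci_high,
    )
    gof = gof_test(spectrum, min_expected=config.min_expected)
    log.info("chi2 = %.3f, df = %d, p = %.3f", gof.statistic, gof.df, gof.p_value)

    rates: list[RateEstimate] = [
        rate_estimate(
            fit.lambda_hat,
            config.elapsed_years,
            gt,
            config.heterozygote_frequency,
        )
        for gt in config.generation_times
    ]
    for r in rates:
        log.info(
            "generation time %.0f y: detectable %.4f, corrected %.4f per generation",
            r.generation_time,
            r.detectable,
            r.corrected,
        )

    t_values = sorted(
        {int(round(config.elapsed_years / gt)) for gt in config.generation_times}
    )
    grid = ne_grid(config.n0_grid, config.r0_grid, config.k, t_values)
    log.info(
        "harmonic-mean Ne over grid: %.0f .. %.0f",
        grid.attrs["ne_min"],
        grid.attrs["ne_max"],
    )

    return Report(
        spectrum=spectrum.counts,
        n=spectrum.n,
        lambda_hat=fit.lambda_hat,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        alpha=fit.alpha,
        gof_statistic=gof.statistic,
        gof_df=gof.df,
        gof_p=gof.p_value,
        gof_bins=tuple(
            {
                "k_lo": b.k_lo,
                "k_hi": b.k_hi,
                "observed": b.observed,
                "expected": b.expected,
            }
            for b in gof.merged_bins
        ),
        rates=tuple(dataclasses.asdict(r) for r in rates),
        ne_table=tuple(grid.to_dict("records")),
        ne_min=grid.attrs["ne_min"],
        ne_max=grid.attrs["ne_max"],
        version=__version__,
        # JSON-native echo (tuples become lists) so serialisation round-trips
        config=json.loads(json.dumps(dataclasses.asdict(config))),
    )
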