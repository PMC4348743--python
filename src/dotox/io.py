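"""File formats, sample QC and adapters.

All tabular I/O is header-first UTF-8 CSV with documented column names and
empty fields for missing values:

* phenotype CSV: mouse_id,cohort,exposure_ppm,pre_pb_mnret,post_pb_mnret,post_bm_mnret,pct_ret
* genotype CSV: rows = markers, columns = mice, cells in {A,H,B,N}
* marker-map CSV: marker,chr,pos_Mb
* dosage CSV (long): mouse,marker,founder,dosage; a compact ``.npz`` cache
  stores the same array for fast reload
* truth JSON: QTL spec, variance components and dose-response parameters
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CALL_SYMBOLS,
    FOUNDER_IDS,
    FounderGenomes,
    HaplotypeDosage,
    validate_marker_map,
)

PHENOTYPE_COLUMNS = (
    "mouse_id",
    "cohort",
    "exposure_ppm",
    "pre_pb_mnret",
    "post_pb_mnret",
    "post_bm_mnret",
    "pct_ret",
)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    table.loc[:, PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    return table


def write_genotypes(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index_label="marker")


def read_genotypes(path) -> pd.DataFrame:
    calls = pd.read_csv(path, index_col="marker", dtype=str)
    bad = set(np.unique(calls.to_numpy())) - set(CALL_SYMBOLS)
    if bad:
        raise ValueError(f"unexpected genotype symbols: {sorted(bad)}")
    return calls


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    validate_marker_map(marker_map)
    marker_map.to_csv(path, index=False)


def read_marker_map(path) -> pd.DataFrame:
    return validate_marker_map(pd.read_csv(path))


def write_truth(truth: dict, path) -> None:
    def default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=default))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_dosages(dosages: HaplotypeDosage, csv_path=None, cache_path=None) -> None:
    """Long-format CSV (mouse,marker,founder,dosage) and/or a compact binary
    ``.npz`` cache (arrays: dosages, mouse_ids, plus the marker map columns).
    Either output may be omitted; the cache is preferred for large runs."""
    if csv_path is None and cache_path is None:
        raise ValueError("provide csv_path and/or cache_path")
    if csv_path is not None:
        dosages.to_long().to_csv(csv_path, index=False, float_format="%.5f")
    if cache_path is not None:
        np.savez_compressed(
            cache_path,
            dosages=dosages.dosages,
            mouse_ids=np.asarray(dosages.mouse_ids, dtype=object),
            marker=dosages.marker_map["marker"].to_numpy(dtype=object),
            chrom=dosages.marker_map["chr"].to_numpy(),
            pos_Mb=dosages.marker_map["pos_Mb"].to_numpy(float),
        )


def read_dosages_cache(cache_path) -> HaplotypeDosage:
    with np.load(cache_path, allow_pickle=True) as z:
        marker_map = pd.DataFrame(
            {"marker": z["marker"], "chr": z["chrom"], "pos_Mb": z["pos_Mb"]}
        )
        return HaplotypeDosage(
            mouse_ids=list(z["mouse_ids"]),
            marker_map=marker_map,
            dosages=z["dosages"],
        )


def read_dosages_long(csv_path, marker_map: pd.DataFrame) -> HaplotypeDosage:
    return HaplotypeDosage.from_long(pd.read_csv(csv_path), marker_map)


def write_founders(founders: FounderGenomes, allele_path, meta_path) -> None:
    """Founder allele table (rows = markers, columns = founders, values 0/1)
    plus a JSON sidecar with the private-founder metadata."""
    frame = pd.DataFrame(
        founders.alleles,
        index=founders.marker_map["marker"].to_numpy(),
        columns=list(founders.founder_ids),
    )
    frame.to_csv(allele_path, index_label="marker")
    chrom, lo, hi = founders.private_interval
    Path(meta_path).write_text(
        json.dumps(
            {
                "private_founder": founders.private_founder,
                "private_interval": [int(chrom), float(lo), float(hi)],
            },
            indent=2,
        )
    )


def read_founders(allele_path, meta_path, marker_map: pd.DataFrame) -> FounderGenomes:
    frame = pd.read_csv(allele_path, index_col="marker")
    if list(frame.columns) != list(FOUNDER_IDS):
        raise ValueError(f"founder columns must be {FOUNDER_IDS}")
    markers = marker_map["marker"].to_numpy()
    missing = [m for m in markers if m not in frame.index]
    if missing:
        raise ValueError(f"founder table missing markers: {missing[:5]}")
    meta = json.loads(Path(meta_path).read_text())
    chrom, lo, hi = meta["private_interval"]
    return FounderGenomes(
        founder_ids=FOUNDER_IDS,
        alleles=frame.loc[markers].to_numpy(dtype=np.int8),
        marker_map=marker_map,
        private_founder=meta["private_founder"],
        private_interval=(chrom, lo, hi),
    )


def qc_filter(
    genotypes: pd.DataFrame, call_rate_threshold: float = 0.90
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove samples whose non-missing call fraction falls below threshold.

    Returns (filtered genotype table, report) where the report lists every
    sample's call rate and whether it was removed.
    """
    if not (0.0 < call_rate_threshold <= 1.0):
        raise ValueError("call_rate_threshold must be in (0, 1]")
    calls = genotypes.to_numpy()
    bad = set(np.unique(calls)) - set(CALL_SYMBOLS)
    if bad:
        raise ValueError(f"unexpected genotype symbols: {sorted(bad)}")
    rates = (calls != "N").mean(axis=0)
    report = pd.DataFrame(
        {
            "mouse_id": genotypes.columns,
            "call_rate": rates,
            "removed": rates < call_rate_threshold,
        }
    )
    kept = genotypes.loc[:, ~report["removed"].to_numpy()]
    return kept, report


def adapt_deposited_phenotypes(frame: pd.DataFrame, column_map: dict) -> pd.DataFrame:
    """Best-effort adapter mapping externally deposited phenotype columns onto
    the package dialect.  ``column_map`` maps source column -> package column;
    a missing source column is reported by name."""
    out = {}
    for src, dst in column_map.items():
        if dst not in PHENOTYPE_COLUMNS:
            raise ValueError(f"unknown target column {dst!r}")
        if src not in frame.columns:
            raise KeyError(f"deposited file lacks expected column {src!r}")
        out[dst] = frame[src]
    missing = [c for c in PHENOTYPE_COLUMNS if c not in out]
    if missing:
        raise ValueError(f"column map leaves phenotype columns unmapped: {missing}")
    return pd.DataFrame(out)
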