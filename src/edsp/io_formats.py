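"""On-disk formats: LINKAGE-style pre-makeped .ped genotype files, marker
map TSVs, phenotype CSVs and results TSVs.

The .ped dialect is whitespace-delimited, one individual per line:

    FamID IndID FatherID MotherID Sex Pheno  A1 B1  A2 B2 ...

with sex coded 1 = male, 2 = female, 0 = unknown, a single placeholder
phenotype column, and two integer allele columns per marker (0 = missing).
Phenotypes travel in a separate CSV because each subject carries several
(SBP, DBP and derived pulse pressure).
"""

from __future__ import annotations

import importlib.resources
import logging
from typing import Iterable, Sequence

import pandas as pd

from .models import (
    FormatError,
    IndividualRecord,
    MarkerDef,
    MarkerMap,
    sort_genotype,
)

log = logging.getLogger(__name__)

_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_CODE_FROM_SEX = {"male": "1", "female": "2", "unknown": "0"}

MAP_COLUMNS = {"name", "chromosome", "theta", "n_alleles",
               "allele_freqs", "bp_range"}
PHENO_COLUMNS = {"family_id", "individual_id", "sex", "age", "sbp", "dbp"}


def read_ped(path) -> list[IndividualRecord]:
    """Parse a pre-makeped .ped file into genotype-only records."""
    records: list[IndividualRecord] = []
    seen: set[tuple[str, str]] = set()
    n_markers = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 columns")
            fam, ind, father, mother, sex_code, _pheno = fields[:6]
            allele_cols = fields[6:]
            if len(allele_cols) % 2:
                raise FormatError(
                    f"{path}:{lineno}: odd allele-column count "
                    f"({len(allele_cols)})")
            if n_markers is None:
                n_markers = len(allele_cols) // 2
            elif len(allele_cols) // 2 != n_markers:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_markers} markers, "
                    f"found {len(allele_cols) // 2}")
            if (fam, ind) in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate individual ({fam}, {ind})")
            seen.add((fam, ind))
            try:
                alleles = [int(a) for a in allele_cols]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer allele") from exc
            if any(a < 0 for a in alleles):
                raise FormatError(f"{path}:{lineno}: negative allele code")
            if sex_code not in _SEX_FROM_CODE:
                raise FormatError(
                    f"{path}:{lineno}: bad sex code {sex_code!r}")
            genotypes = [sort_genotype(alleles[2 * i], alleles[2 * i + 1])
                         for i in range(len(alleles) // 2)]
            records.append(IndividualRecord(
                family_id=fam, individual_id=ind, father_id=father,
                mother_id=mother, sex=_SEX_FROM_CODE[sex_code],
                genotypes=genotypes))
    return records


def write_ped(records: Iterable[IndividualRecord], path) -> None:
    """Inverse of :func:`read_ped`; alleles written smaller-first."""
    with open(path, "w") as fh:
        for rec in records:
            cols = [rec.family_id, rec.individual_id, rec.father_id,
                    rec.mother_id, _CODE_FROM_SEX[rec.sex], "0"]
            for a, b in rec.genotypes:
                lo, hi = sort_genotype(a, b)
                cols.extend([str(lo), str(hi)])
            fh.write(" ".join(cols) + "\n")


def read_marker_map(path) -> MarkerMap:
    """Read a marker map TSV (name, chromosome, theta, n_alleles,
    optional comma-separated allele_freqs, optional bp_range)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    unknown = set(df.columns) - MAP_COLUMNS
    if unknown:
        raise FormatError(
            f"{path}: unknown marker-map column(s): {sorted(unknown)}")
    required = {"name", "chromosome", "theta", "n_alleles"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing marker-map column(s): {sorted(missing)}")
    markers = []
    for _, row in df.iterrows():
        freqs: tuple[float, ...] = ()
        if "allele_freqs" in df.columns and isinstance(row.get("allele_freqs"), str):
            freqs = tuple(float(x) for x in row["allele_freqs"].split(","))
        bp = row.get("bp_range") if "bp_range" in df.columns else None
        if not isinstance(bp, str) or not bp:
            bp = None
        markers.append(MarkerDef(
            name=row["name"], chromosome=str(row["chromosome"]),
            theta=float(row["theta"]), n_alleles=int(row["n_alleles"]),
            allele_freqs=freqs, bp_range=bp))
    return MarkerMap(markers)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    rows = []
    for m in marker_map:
        rows.append({
            "name": m.name, "chromosome": m.chromosome,
            "theta": repr(m.theta), "n_alleles": m.n_alleles,
            "allele_freqs": ",".join(repr(f) for f in m.allele_freqs),
            "bp_range": m.bp_range if m.bp_range is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def table1_markers() -> MarkerMap:
    """The packaged chromosome 11/17 microsatellite panel (names,
    chromosomes and fragment-size ranges as metadata; 8 equifrequent
    alleles and theta = 0.5 by convention, since no map distances are
    published for this panel)."""
    ref = importlib.resources.files("edsp.data") / "markers_table1.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_marker_map(path)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV keyed by (family_id, individual_id).

    Required columns: family_id, individual_id, sex, age, sbp, dbp.
    Extra columns (height, weight, serum markers, ...) pass through
    untouched.  A derived ``pp`` column is added when absent.
    """
    df = pd.read_csv(path, dtype={"family_id": str, "individual_id": str})
    missing = PHENO_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing phenotype column(s): {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: no phenotype rows")
    if "pp" not in df.columns:
        df["pp"] = df["sbp"] - df["dbp"]
    return df.set_index(["family_id", "individual_id"], drop=False)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def attach_phenotypes(records: Sequence[IndividualRecord],
                      pheno: pd.DataFrame) -> int:
    """Join phenotype rows onto ped records in place.

    Phenotype rows without a matching ped individual are dropped with a
    logged count; returns the number of records that received phenotypes.
    """
    by_key = {rec.key: rec for rec in records}
    matched = 0
    dropped = 0
    for key, row in pheno.iterrows():
        rec = by_key.get(key)
        if rec is None:
            dropped += 1
            continue
        rec.sbp = float(row["sbp"])
        rec.dbp = float(row["dbp"])
        rec.age = float(row["age"]) if pd.notna(row["age"]) else None
        matched += 1
    if dropped:
        log.warning("dropped %d phenotype row(s) without a ped individual",
                    dropped)
    return matched


def write_results(table: pd.DataFrame, path) -> None:
    """Write an analysis results table as TSV, floats at 12 significant
    digits so that re-reading is numerically lossless at that precision."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def cohort_phenotype_frame(individuals: Iterable[IndividualRecord]) -> pd.DataFrame:
    """Phenotype CSV content for a simulated cohort's offspring."""
    rows = []
    for ind in individuals:
        if ind.sbp is None:
            continue
        rows.append({
            "family_id": ind.family_id, "individual_id": ind.individual_id,
            "sex": ind.sex, "age": ind.age, "sbp": ind.sbp, "dbp": ind.dbp,
            "pp": ind.pp,
        })
    return pd.DataFrame(rows)
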