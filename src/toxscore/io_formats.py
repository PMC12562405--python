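"""Readers, writers and identifier handling for the pipeline's external artifacts.

Covers TCGA-style sample barcodes, HGNC-style gene-symbol harmonization,
tab-separated expression and clinical tables, GMT pathway collections, and
chemical–gene interaction exports from curated toxicogenomic databases.
All tabular output is tab-separated UTF-8 text with a ``#``-prefixed
provenance header line.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR_CODE = "01"
NORMAL_CODE = "11"

__all__ = [
    "SampleBarcode",
    "ExpressionMatrix",
    "ClinicalRecord",
    "GeneSetCollection",
    "BarcodeError",
    "parse_barcode",
    "harmonize_symbol",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "read_gmt",
    "read_ctd_export",
    "read_synonym_table",
    "write_table",
    "provenance_header",
]


class BarcodeError(ValueError):
    """Raised for malformed TCGA-style sample barcodes."""


@dataclass(frozen=True)
class SampleBarcode:
    """A TCGA-style barcode split into its analytic components.

    ``full`` is the original string; ``short`` is the
    project-tss-participant-sampletype prefix used for clinical joins;
    ``sample_type_code`` is the two-character 4th field ("01" primary
    tumor, "11" solid tissue normal).
    """

    full: str
    short: str
    sample_type_code: str

    @property
    def is_tumor(self) -> bool:
        return self.sample_type_code == TUMOR_CODE

    @property
    def is_normal(self) -> bool:
        return self.sample_type_code == NORMAL_CODE

    @property
    def participant(self) -> str:
        return "-".join(self.short.split("-")[:3])


def parse_barcode(raw: str) -> SampleBarcode:
    """Split a dash-delimited barcode; classify by the 4th field.

    "TCGA-AB-1234-01" is a primary tumor, "TCGA-AB-1234-11" a solid
    tissue normal. Any two-character 4th field is accepted here;
    filtering to {"01", "11"} is the caller's decision.

    Raises
    ------
    BarcodeError
        If fewer than 4 dash fields, or the 4th field does not start
        with a 2-digit sample-type code.
    """
    fields = raw.strip().split("-")
    if len(fields) < 4:
        raise BarcodeError(f"malformed barcode {raw!r}: fewer than 4 dash-delimited fields")
    code = fields[3][:2]
    if len(fields[3]) < 2 or not code.isdigit():
        raise BarcodeError(f"malformed barcode {raw!r}: 4th field {fields[3]!r} lacks a 2-digit sample-type code")
    short = "-".join(fields[:3] + [code])
    return SampleBarcode(full=raw.strip(), short=short, sample_type_code=code)


class WithdrawnSymbolError(ValueError):
    """Raised when a symbol maps to 'withdrawn, no replacement'."""


WITHDRAWN = "-"  # sentinel value in synonym tables for withdrawn symbols


def harmonize_symbol(raw: str, synonym_table: dict[str, str] | None = None) -> str:
    """Harmonize a gene symbol: trim, uppercase, resolve synonyms.

    Idempotent: harmonizing an already-harmonized symbol is a no-op.
    The synonym table maps legacy/alias symbols (upper-case keys) to
    approved symbols; a value of ``"-"`` marks a withdrawn symbol with
    no replacement and raises :class:`WithdrawnSymbolError`.
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol after trimming")
    if synonym_table:
        seen = {sym}
        while sym in synonym_table:
            target = synonym_table[sym]
            if target == WITHDRAWN:
                raise WithdrawnSymbolError(f"symbol {raw!r} is withdrawn with no replacement")
            target = target.strip().upper()
            if target in seen:  # cycle guard
                break
            seen.add(target)
            sym = target
    return sym


def read_synonym_table(path) -> dict[str, str]:
    """Read a two-column tab-separated alias -> approved symbol table."""
    table: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"synonym table line {i}: expected 2 tab-separated fields")
            table[parts[0].strip().upper()] = parts[1].strip()
    return table


@dataclass
class ExpressionMatrix:
    """Gene × sample log2-scale expression with a tumor/normal partition.

    ``values`` is a pandas DataFrame indexed by harmonized gene symbol
    with barcoded sample columns. Invariants enforced at construction:
    unique gene symbols, unique short barcodes, non-zero variance per
    gene across retained samples.
    """

    values: pd.DataFrame
    barcodes: list[SampleBarcode] = field(default_factory=list)

    def __post_init__(self):
        if not self.barcodes:
            self.barcodes = [parse_barcode(c) for c in self.values.columns]
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        shorts = [b.short for b in self.barcodes]
        if len(set(shorts)) != len(shorts):
            raise ValueError("duplicate short barcodes among samples")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tumor_columns(self) -> list[str]:
        return [b.full for b in self.barcodes if b.is_tumor]

    @property
    def normal_columns(self) -> list[str]:
        return [b.full for b in self.barcodes if b.is_normal]

    @property
    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_columns]

    @property
    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ClinicalRecord:
    """Per-participant clinical covariates and per-endpoint survival.

    ``endpoints`` maps endpoint name (OS/PFI/DFI/DSS) to a
    (time_days, status) pair; either member may be None when missing.
    ``stage`` is one of "I", "II", "III", "IV" or None (missing).
    """

    short_barcode: str
    age_years: float | None
    sex: str | None  # "male" | "female"
    stage: str | None
    endpoints: dict[str, tuple[float | None, int | None]] = field(default_factory=dict)


_STAGE_NORMALIZATION = {
    "I": "I", "II": "II", "III": "III", "IV": "IV",
    "STAGE I": "I", "STAGE II": "II", "STAGE III": "III", "STAGE IV": "IV",
    "1": "I", "2": "II", "3": "III", "4": "IV",
}

_SEX_NORMALIZATION = {"MALE": "male", "M": "male", "FEMALE": "female", "F": "female"}


def normalize_stage(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    token = str(raw).strip().upper()
    if token in ("", "NA", "NAN", "MISSING", "[DISCREPANCY]", "[NOT AVAILABLE]"):
        return None
    if token in _STAGE_NORMALIZATION:
        return _STAGE_NORMALIZATION[token]
    raise ValueError(f"unrecognized stage token {raw!r}")


DEFAULT_CLINICAL_COLUMNS = {
    "barcode": "short_barcode",
    "age": "age_years",
    "sex": "sex",
    "stage": "stage",
}

ENDPOINTS = ("OS", "PFI", "DFI", "DSS")


def read_clinical_tsv(path, columns: dict[str, str] | None = None) -> list[ClinicalRecord]:
    """Read a clinical/survival table keyed by short barcode.

    ``columns`` maps logical names (barcode, age, sex, stage) to header
    names; endpoint columns are expected as ``<EP>_time`` /
    ``<EP>_status`` for EP in OS/PFI/DFI/DSS (missing columns are
    simply absent endpoints).
    """
    cols = dict(DEFAULT_CLINICAL_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for logical in ("barcode",):
        if cols[logical] not in df.columns:
            raise ValueError(f"clinical table missing required column {cols[logical]!r}")
    records = []
    for _, row in df.iterrows():
        age = row.get(cols["age"])
        age_years = float(age) if age not in (None, "", "NA") and not pd.isna(age) else None
        sex_raw = row.get(cols["sex"])
        if sex_raw is None or pd.isna(sex_raw) or str(sex_raw).strip() == "":
            sex = None
        else:
            token = str(sex_raw).strip().upper()
            if token not in _SEX_NORMALIZATION:
                raise ValueError(f"unknown sex token {sex_raw!r}")
            sex = _SEX_NORMALIZATION[token]
        stage = normalize_stage(row.get(cols["stage"]))
        endpoints = {}
        for ep in ENDPOINTS:
            tcol, scol = f"{ep}_time", f"{ep}_status"
            if tcol in df.columns and scol in df.columns:
                t_raw, s_raw = row[tcol], row[scol]
                t = None if pd.isna(t_raw) or t_raw == "" else float(t_raw)
                s = None if pd.isna(s_raw) or s_raw == "" else int(float(s_raw))
                if t is not None and t < 0:
                    raise ValueError(f"negative {ep} time {t} for {row[cols['barcode']]}")
                if s is not None and s not in (0, 1):
                    raise ValueError(f"{ep} status {s} not in {{0,1}}")
                endpoints[ep] = (t, s)
        records.append(
            ClinicalRecord(
                short_barcode=str(row[cols["barcode"]]).strip(),
                age_years=age_years,
                sex=sex,
                stage=stage,
                endpoints=endpoints,
            )
        )
    return records


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (term -> description, members)."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]


def read_gmt(path, name: str | None = None, synonym_table: dict[str, str] | None = None) -> GeneSetCollection:
    """Read a standard GMT file (term, description, members...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {i}: expected >=3 tab-separated fields, got {len(parts)}")
            term, desc = parts[0], parts[1]
            if term in sets:
                raise ValueError(f"GMT line {i}: duplicate term name {term!r}")
            members = frozenset(harmonize_symbol(s, synonym_table) for s in parts[2:] if s.strip())
            sets[term] = (desc, members)
    return GeneSetCollection(name=name or str(path), sets=sets)


def read_ctd_export(
    path,
    organism_filter: str = "Homo sapiens",
    gene_column: str = "GeneSymbol",
    organism_column: str = "Organism",
    synonym_table: dict[str, str] | None = None,
) -> frozenset[str]:
    """Read a chemical–gene interaction export and collapse to a gene set.

    Rows are filtered to ``organism_filter``; multiple interaction rows
    per gene collapse to a single set member; symbols are harmonized.
    Interaction qualifiers are ignored for set membership. Symbols that
    resolve to "withdrawn, no replacement" are excluded (logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (gene_column, organism_column):
        if col not in df.columns:
            raise ValueError(f"chemical–gene export missing configured column {col!r}")
    df = df[df[organism_column].str.strip() == organism_filter]
    genes: set[str] = set()
    n_withdrawn = 0
    for raw in df[gene_column]:
        if raw is None or pd.isna(raw) or not str(raw).strip():
            continue
        try:
            genes.add(harmonize_symbol(str(raw), synonym_table))
        except WithdrawnSymbolError:
            n_withdrawn += 1
    if n_withdrawn:
        logger.info("excluded %d withdrawn gene symbols from chemical export", n_withdrawn)
    return frozenset(genes)


def read_expression_tsv(
    path,
    orientation: str = "genes_by_samples",
    synonym_table: dict[str, str] | None = None,
    log2_offset: float | None = None,
) -> ExpressionMatrix:
    """Read a gene × sample expression TSV into an :class:`ExpressionMatrix`.

    QC applied (all logged): duplicate gene rows collapsed by mean of
    log2 values; zero-variance genes dropped; samples whose barcode
    sample-type code is neither "01" nor "11" dropped; malformed
    barcodes rejected. ``log2_offset``, if given, applies
    ``log2(x + offset)`` for matrices supplied as raw normalized counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")

    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
        raise ValueError(f"non-numeric expression value at gene {list(row)}, sample {col!r}")

    if log2_offset is not None:
        df = np.log2(df + log2_offset)

    # drop samples outside the tumor/normal partition
    keep_cols, barcodes = [], []
    for col in df.columns:
        bc = parse_barcode(col)  # malformed barcode -> BarcodeError
        if bc.sample_type_code in (TUMOR_CODE, NORMAL_CODE):
            keep_cols.append(col)
            barcodes.append(bc)
        else:
            logger.warning("dropping sample %s with sample-type code %s", col, bc.sample_type_code)
    df = df[keep_cols]

    df.index = [harmonize_symbol(str(g), synonym_table) for g in df.index]
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean of log2 values", n_dup)
        df = df.groupby(level=0, sort=False).mean()

    variances = df.var(axis=1, ddof=0)
    flat = variances == 0
    if flat.any():
        logger.info("dropping %d zero-variance genes", int(flat.sum()))
        df = df.loc[~flat]

    return ExpressionMatrix(values=df, barcodes=barcodes)


def provenance_header(seed=None, config_hash: str | None = None) -> str:
    from toxscore import __version__

    parts = [f"# toxscore v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config object."""
    import json

    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash: str | None = None, index: bool = True) -> None:
    """Write a tab-separated table with a ``#`` provenance header."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(provenance_header(seed, cfg_hash) + "\n")
        # %.17g guarantees float64 values survive the text round trip
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n", float_format="%.17g")


def write_expression_tsv(matrix: ExpressionMatrix, path, seed=None, cfg_hash: str | None = None) -> None:
    write_table(matrix.values, path, seed=seed, cfg_hash=cfg_hash, index=True)
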