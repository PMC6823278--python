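"""SNP risk-marker catalog: loading, validation and filtering.

A marker is one literature-derived risk factor: an rsID, its risk allele,
the risk-allele frequency in the target population, and the published odds
ratio of the heterozygous genotype (plus, when reported, the homozygous
risk genotype). Catalogs are ordered, immutable collections of markers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "SNPMarker",
    "MarkerCatalog",
    "MarkerTableError",
    "read_marker_table",
    "write_marker_table",
    "filter_by_or",
    "hwe_genotype_freqs",
    "load_lung_cancer_catalog",
]

_VALID_ALLELES = frozenset("ACGT")

#: Default odds-ratio lower bound used when curating markers.
DEFAULT_OR_THRESHOLD = 1.15


class MarkerTableError(ValueError):
    """Raised when a marker table row fails validation; names the row."""


@dataclass(frozen=True)
class SNPMarker:
    """One SNP risk factor.

    Parameters
    ----------
    snp_id:
        dbSNP rsID (any non-empty label is accepted).
    risk_allele:
        The allele whose carriage increases disease odds; one of A/C/G/T.
    freq:
        Risk-allele frequency in the target population, in (0, 1).
    or_het:
        Published odds ratio of the heterozygous genotype vs. non-carriers.
    or_hom:
        Odds ratio of the homozygous risk genotype, or ``None`` when the
        literature reports no homozygous estimate.
    freq_all:
        Optional risk-allele frequency across all populations; stored for
        provenance, never used by the model.
    source:
        Free-text citation.
    """

    snp_id: str
    risk_allele: str
    freq: float
    or_het: float
    or_hom: Optional[float] = None
    freq_all: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.risk_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.snp_id}: risk_allele must be one of A/C/G/T, "
                f"got {self.risk_allele!r}"
            )
        if not 0.0 < self.freq < 1.0:
            raise ValueError(f"{self.snp_id}: freq must lie in (0, 1), got {self.freq}")
        if self.or_het <= 0.0:
            raise ValueError(f"{self.snp_id}: or_het must be > 0, got {self.or_het}")
        if self.or_hom is not None and self.or_hom <= 0.0:
            raise ValueError(f"{self.snp_id}: or_hom must be > 0, got {self.or_hom}")


@dataclass(frozen=True)
class MarkerCatalog:
    """Ordered, duplicate-free collection of :class:`SNPMarker`."""

    markers: tuple[SNPMarker, ...]
    population_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        seen: set[str] = set()
        for m in self.markers:
            if m.snp_id in seen:
                raise ValueError(f"duplicate snp_id in catalog: {m.snp_id}")
            seen.add(m.snp_id)

    def __iter__(self) -> Iterator[SNPMarker]:
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, snp_id: str) -> SNPMarker:
        for m in self.markers:
            if m.snp_id == snp_id:
                return m
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(m.snp_id for m in self.markers)

    def provenance_hash(self) -> str:
        """SHA-256 over the catalog's model-relevant fields (hex digest)."""
        h = hashlib.sha256()
        for m in self.markers:
            h.update(
                f"{m.snp_id}\t{m.risk_allele}\t{m.freq!r}\t{m.or_het!r}\t"
                f"{m.or_hom!r}\n".encode()
            )
        return h.hexdigest()


def _parse_float(value: object, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise MarkerTableError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


def _is_na(value: object) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    return isinstance(value, str) and value.strip().upper() in {"", "NA"}


def read_marker_table(
    path: str | Path, dialect: str | None = None, population_label: str = ""
) -> MarkerCatalog:
    """Read a marker table (TSV or CSV) into a validated catalog.

    Required columns: ``snp_id, risk_allele, freq, or_het, or_hom, source``.
    A missing homozygous OR is an empty cell or the literal ``NA``. An
    optional ``freq_all`` column is stored for provenance. Row order is
    preserved. Malformed rows raise :class:`MarkerTableError` naming the
    1-based data-row number.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in {"tsv", "csv"}:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    required = {"snp_id", "risk_allele", "freq", "or_het", "or_hom", "source"}
    missing = required - set(df.columns)
    if missing:
        raise MarkerTableError(f"missing required columns: {sorted(missing)}")

    markers: list[SNPMarker] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        snp_id = str(rec["snp_id"]).strip()
        if snp_id in seen:
            raise MarkerTableError(f"row {i}: duplicate rsID {snp_id!r}")
        seen.add(snp_id)
        or_hom = None if _is_na(rec["or_hom"]) else _parse_float(rec["or_hom"], "or_hom", i)
        freq_all = None
        if "freq_all" in rec and not _is_na(rec["freq_all"]):
            freq_all = _parse_float(rec["freq_all"], "freq_all", i)
        try:
            markers.append(
                SNPMarker(
                    snp_id=snp_id,
                    risk_allele=str(rec["risk_allele"]).strip().upper(),
                    freq=_parse_float(rec["freq"], "freq", i),
                    or_het=_parse_float(rec["or_het"], "or_het", i),
                    or_hom=or_hom,
                    freq_all=freq_all,
                    source=str(rec["source"]).strip(),
                )
            )
        except ValueError as exc:
            raise MarkerTableError(f"row {i}: {exc}") from exc
    return MarkerCatalog(markers=tuple(markers), population_label=population_label)


def write_marker_table(catalog: MarkerCatalog, path: str | Path, dialect: str = "tsv") -> None:
    """Write a catalog back to TSV/CSV in the dialect ``read_marker_table`` reads."""
    sep = "\t" if dialect == "tsv" else ","
    rows = []
    for m in catalog:
        rows.append(
            {
                "snp_id": m.snp_id,
                "risk_allele": m.risk_allele,
                "freq": repr(m.freq),
                "freq_all": "" if m.freq_all is None else repr(m.freq_all),
                "or_het": repr(m.or_het),
                "or_hom": "NA" if m.or_hom is None else repr(m.or_hom),
                "source": m.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def filter_by_or(catalog: MarkerCatalog, threshold: float = DEFAULT_OR_THRESHOLD) -> MarkerCatalog:
    """Retain markers whose heterozygous OR is >= ``threshold``.

    The curation convention drops weak markers (conventionally OR < 1.15).
    The filter looks at ``or_het`` only; order is preserved and a new
    catalog is returned (an empty result is legal).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    kept = tuple(m for m in catalog if m.or_het >= threshold)
    return replace(catalog, markers=kept)


def hwe_genotype_freqs(freq: float) -> tuple[float, float]:
    """Heterozygote and risk-homozygote frequencies under Hardy-Weinberg.

    For risk-allele frequency ``f`` returns ``(2 f (1-f), f**2)``.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError(f"freq must lie in (0, 1), got {freq}")
    return 2.0 * freq * (1.0 - freq), freq * freq


def load_lung_cancer_catalog() -> MarkerCatalog:
    """The packaged eight-SNP lung-cancer marker set for Chinese individuals."""
    from importlib.resources import files

    path = files("snprisk.data").joinpath("lung_cancer_chinese.tsv")
    return read_marker_table(str(path), dialect="tsv", population_label="Chinese")
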