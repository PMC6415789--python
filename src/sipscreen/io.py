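"""Tabular I/O for SIP amplicon screens.

Reads and writes the formats the pipeline touches: OTU count tables in the
mothur ``shared`` dialect (samples as rows, OTUs as columns, with ``label``,
``Group`` and ``numOtus`` header columns) and as plain TSV matrices (taxa as
rows), mothur ``cons.taxonomy``-style lineage tables, per-sample fraction
metadata as YAML, and the final labelled-taxon report.

The central container is :class:`SipCountTable`: an integer taxa x samples
count matrix with ordered identifiers and, optionally, per-sample
:class:`FractionMeta` describing which gradient fraction each amplicon sample
came from (isotope, heavy/light role, treatment, buoyant density).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "FractionMeta",
    "SipCountTable",
    "TaxonomyMap",
    "read_shared_table",
    "write_count_table",
    "read_taxonomy",
    "read_fraction_meta",
    "write_fraction_meta",
    "write_label_report",
    "significance_stars",
]

#: Lineage ranks, domain through genus, used by :class:`TaxonomyMap`.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Marker for ranks where no classification is available.
UNCLASSIFIED = "unclassified"

_ISOTOPES = ("C12", "C13")
_ROLES = ("heavy", "light", "other")

#: Physically plausible CsCl buoyant densities for DNA, g/mL.
_DENSITY_RANGE = (1.60, 1.80)


@dataclass(frozen=True)
class FractionMeta:
    """Metadata for one sequenced gradient-fraction sample.

    Parameters
    ----------
    isotope
        Carbon source of the incubation this fraction came from: ``"C12"``
        (natural abundance control) or ``"C13"`` (labelled substrate).
    fraction_role
        Position in the density gradient: ``"heavy"`` (~1.725 g/mL),
        ``"light"`` (~1.700 g/mL) or ``"other"``.
    treatment
        Free-text substrate label, e.g. ``"starch"`` or ``"hemicellulose"``.
    density
        Measured buoyant density of the fraction in g/mL, if known.
    """

    isotope: str
    fraction_role: str
    treatment: str
    density: float | None = None

    def __post_init__(self) -> None:
        if self.isotope not in _ISOTOPES:
            raise ValidationError(
                f"isotope must be one of {_ISOTOPES}, got {self.isotope!r}"
            )
        if self.fraction_role not in _ROLES:
            raise ValidationError(
                f"fraction_role must be one of {_ROLES}, got {self.fraction_role!r}"
            )
        if self.density is not None and not (
            _DENSITY_RANGE[0] <= self.density <= _DENSITY_RANGE[1]
        ):
            raise ValidationError(
                f"density {self.density} g/mL outside plausible CsCl range "
                f"{_DENSITY_RANGE}"
            )


@dataclass
class SipCountTable:
    """Integer read-count matrix (taxa x samples) with ordered identifiers.

    ``meta`` maps each sample id to its :class:`FractionMeta`; it may be
    ``None`` for tables that have not yet been annotated with the gradient
    layout (parsers return un-annotated tables; the screen requires
    annotation).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    meta: dict[str, FractionMeta] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.asarray(counts, dtype=float) == np.floor(np.asarray(counts, dtype=float))):
                bad = np.argwhere(np.asarray(counts, dtype=float) != np.floor(np.asarray(counts, dtype=float)))
                r, c = bad[0]
                raise ValidationError(
                    f"non-integer count at OTU {self.otu_ids[r]!r}, "
                    f"sample {self.sample_ids[c]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.otu_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        self.counts = counts.astype(np.int64, copy=False)
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids in count table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in count table")
        if self.meta is not None:
            missing = set(self.sample_ids) - set(self.meta)
            extra = set(self.meta) - set(self.sample_ids)
            if missing or extra:
                raise ValidationError(
                    f"fraction metadata mismatch: missing {sorted(missing)}, "
                    f"unknown {sorted(extra)}"
                )

    # -- convenience ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="reads")

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame, taxa as rows, samples as columns."""
        return pd.DataFrame(self.counts.copy(), index=list(self.otu_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, meta: Mapping[str, FractionMeta] | None = None
    ) -> "SipCountTable":
        """Build a table from a taxa x samples DataFrame."""
        return cls(
            otu_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            counts=frame.to_numpy(),
            meta=dict(meta) if meta is not None else None,
        )

    def with_meta(self, meta: Mapping[str, FractionMeta]) -> "SipCountTable":
        """Return a copy annotated with fraction metadata."""
        return replace(self, counts=self.counts.copy(), meta=dict(meta))

    def column(self, sample_id: str) -> np.ndarray:
        j = self.sample_ids.index(sample_id)
        return self.counts[:, j]

    def find_sample(
        self, isotope: str, fraction_role: str, treatment: str | None = None
    ) -> str | None:
        """Return the unique sample id matching (isotope, role[, treatment]).

        Returns ``None`` when absent; raises when ambiguous.
        """
        if self.meta is None:
            return None
        hits = [
            sid
            for sid in self.sample_ids
            if self.meta[sid].isotope == isotope
            and self.meta[sid].fraction_role == fraction_role
            and (treatment is None or self.meta[sid].treatment == treatment)
        ]
        if len(hits) > 1:
            raise ValidationError(
                f"multiple samples match isotope={isotope}, role={fraction_role}, "
                f"treatment={treatment}: {hits}"
            )
        return hits[0] if hits else None

    def treatments(self) -> list[str]:
        if self.meta is None:
            return []
        return sorted({m.treatment for m in self.meta.values()})


class TaxonomyMap:
    """OTU id -> ranked lineage (domain..genus).

    Lookups of unknown OTUs return a fully ``unclassified`` lineage rather
    than raising, so reports can always be rendered.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]] | None = None) -> None:
        self._lineages: dict[str, tuple[str, ...]] = {}
        if lineages:
            for otu, ranks in lineages.items():
                self._lineages[str(otu)] = _pad_lineage(ranks)

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._lineages

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        """Full lineage tuple, padded to genus with ``unclassified``."""
        return self._lineages.get(otu_id, (UNCLASSIFIED,) * len(RANKS))

    def rank_of(self, otu_id: str, rank: str) -> str:
        """The taxon name at ``rank`` (one of :data:`RANKS`)."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineage(otu_id)[RANKS.index(rank)]

    def items(self):
        return self._lineages.items()


def _pad_lineage(ranks: Sequence[str]) -> tuple[str, ...]:
    clean = [r for r in (str(x).strip() for x in ranks) if r]
    clean = clean[: len(RANKS)]
    clean += [UNCLASSIFIED] * (len(RANKS) - len(clean))
    return tuple(clean)


# ---------------------------------------------------------------------------
# count-table parsing
# ---------------------------------------------------------------------------

_DIALECTS = ("mothur_shared", "tsv")


def read_shared_table(
    path: str | Path,
    dialect: str = "mothur_shared",
    meta: Mapping[str, FractionMeta] | None = None,
) -> SipCountTable:
    """Read an OTU count table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"mothur_shared"``: tab-separated with header columns ``label``,
        ``Group``, ``numOtus`` followed by one column per OTU; one row per
        sample (mothur Group). Any ``label`` value is accepted; Group names
        must be unique; ``numOtus`` is validated against the actual number
        of OTU columns.
        ``"tsv"``: plain matrix, taxa as rows, samples as columns, first
        column holding OTU ids.
    meta
        Optional fraction metadata to attach (sample id -> FractionMeta).
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "mothur_shared":
        table = _read_mothur_shared(path)
    else:
        table = _read_plain_tsv(path)
    if meta is not None:
        table = table.with_meta(meta)
    return table


def _read_mothur_shared(path: Path) -> SipCountTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("label", "Group", "numOtus")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"mothur shared file {path} is missing column {col!r}")
    otu_cols = [c for c in df.columns if c not in required]
    n_otus_declared = pd.to_numeric(df["numOtus"], errors="coerce")
    if n_otus_declared.isna().any():
        raise FormatError(f"non-numeric numOtus value in {path}")
    if not (n_otus_declared.astype(int) == len(otu_cols)).all():
        raise ValidationError(
            f"numOtus={sorted(set(n_otus_declared.astype(int)))} does not match "
            f"the {len(otu_cols)} OTU columns present in {path}"
        )
    groups = [str(g) for g in df["Group"]]
    if len(set(groups)) != len(groups):
        raise ValidationError(f"duplicate Group names in {path}")
    counts = _parse_count_block(df[otu_cols], row_ids=groups, col_ids=otu_cols, path=path)
    # shared files are samples x OTUs; our container is taxa x samples
    return SipCountTable(otu_ids=otu_cols, sample_ids=groups, counts=counts.T)


def _read_plain_tsv(path: Path) -> SipCountTable:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    counts = _parse_count_block(df, row_ids=otu_ids, col_ids=sample_ids, path=path)
    return SipCountTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts)


def _parse_count_block(
    block: pd.DataFrame, row_ids: Sequence[str], col_ids: Sequence[str], path: Path
) -> np.ndarray:
    numeric = block.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric count at row {row_ids[r]!r}, column {col_ids[c]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.any(values != np.floor(values)):
        r, c = np.argwhere(values != np.floor(values))[0]
        raise ValidationError(
            f"fractional count {values[r, c]} at row {row_ids[r]!r}, "
            f"column {col_ids[c]!r} in {path}; counts must be integer reads"
        )
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at row {row_ids[r]!r}, column {col_ids[c]!r} in {path}"
        )
    return values.astype(np.int64)


def write_count_table(
    table: SipCountTable, path: str | Path, dialect: str = "mothur_shared", label: str = "0.03"
) -> None:
    """Write a count table in the requested dialect.

    ``label`` fills the mothur ``label`` column (OTU clustering distance);
    real mothur files carry the clustering cutoff there.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "mothur_shared":
        df = pd.DataFrame(table.counts.T, columns=table.otu_ids)
        df.insert(0, "numOtus", table.n_taxa)
        df.insert(0, "Group", table.sample_ids)
        df.insert(0, "label", label)
        df.to_csv(path, sep="\t", index=False)
    else:
        df = table.to_frame()
        df.index.name = "otu"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a mothur ``cons.taxonomy``-style lineage table.

    Expects tab-separated ``OTU<TAB>[Size<TAB>]Taxonomy`` with the lineage as
    semicolon-separated ranks, optionally decorated with bootstrap support in
    parentheses (``Bacteria(100);``). Decorations are stripped and lineages
    padded to genus with ``unclassified``. Duplicate OTU ids are an error.
    """
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0].strip().lower() == "otu":
                continue  # header row
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{line_no}: expected at least two tab-separated "
                    f"columns (otu, taxonomy)"
                )
            otu = parts[0].strip()
            tax = parts[-1]  # tolerate an optional middle Size column
            if otu in lineages:
                raise ValidationError(f"{path}:{line_no}: duplicate OTU id {otu!r}")
            ranks = []
            for token in tax.split(";"):
                token = token.strip()
                if not token:
                    continue
                if "(" in token:
                    token = token[: token.index("(")]
                ranks.append(token.strip(' "'))
            lineages[otu] = _pad_lineage(ranks)
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# fraction metadata (YAML)
# ---------------------------------------------------------------------------


def read_fraction_meta(path: str | Path) -> dict[str, FractionMeta]:
    """Read per-sample fraction metadata from YAML.

    The file is a mapping ``sample_id -> {isotope, fraction_role, treatment,
    density?}`` (optionally nested under a top-level ``samples:`` key).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping of sample ids")
    if "samples" in data and isinstance(data["samples"], dict):
        data = data["samples"]
    meta: dict[str, FractionMeta] = {}
    for sid, fields in data.items():
        if not isinstance(fields, dict):
            raise FormatError(f"{path}: entry for sample {sid!r} is not a mapping")
        unknown = set(fields) - {"isotope", "fraction_role", "treatment", "density"}
        if unknown:
            raise FormatError(f"{path}: unknown keys {sorted(unknown)} for sample {sid!r}")
        try:
            meta[str(sid)] = FractionMeta(
                isotope=str(fields["isotope"]),
                fraction_role=str(fields["fraction_role"]),
                treatment=str(fields.get("treatment", "")),
                density=None if fields.get("density") is None else float(fields["density"]),
            )
        except KeyError as exc:
            raise FormatError(f"{path}: sample {sid!r} is missing key {exc}") from exc
    return meta


def write_fraction_meta(meta: Mapping[str, FractionMeta], path: str | Path) -> None:
    data = {
        sid: {
            "isotope": m.isotope,
            "fraction_role": m.fraction_role,
            "treatment": m.treatment,
            **({"density": m.density} if m.density is not None else {}),
        }
        for sid, m in meta.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# labelled-taxon report
# ---------------------------------------------------------------------------

#: Significance levels annotated with stars in the report, strongest last.
STAR_LEVELS = (0.05, 0.01, 0.001)


def significance_stars(p_values: Sequence[float], levels: Sequence[float] = STAR_LEVELS) -> list[str]:
    """Star annotation per hypothesis: one star per level at which the
    Holm-adjusted decision over the whole family rejects it.

    ``*``: rejected at 0.05, ``**``: at 0.01, ``***``: at 0.001.
    """
    from .screen import holm_bonferroni

    stars = [""] * len(p_values)
    for level in sorted(levels, reverse=True):
        decisions = holm_bonferroni(list(p_values), alpha=level)
        for i, d in enumerate(decisions):
            if d.reject:
                stars[i] += "*"
    return stars


REPORT_COLUMNS = [
    "otu_id",
    "direction",
    "or_c12",
    "or_c13",
    "bd_statistic",
    "df",
    "p_value",
    "holm_rank",
    "holm_threshold",
    "significant",
    "stars",
    "lineage",
]


def write_label_report(
    calls: Iterable,
    taxonomy: TaxonomyMap | None,
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-taxon labelling report as TSV.

    One row per tested taxon, both directions included (heavy-enriched
    "labelled" and light-enriched "unlabelled"), ordered by Holm rank
    (raw p ascending) with ties broken by OTU id. Significance stars follow
    the ``*`` p<0.05 / ``**`` p<0.01 / ``***`` p<0.001 convention, computed
    from Holm-adjusted decisions at each level. Returns the frame written.
    """
    calls = list(calls)
    taxonomy = taxonomy or TaxonomyMap()
    ordered = sorted(calls, key=lambda c: (c.p_raw, c.otu_id))
    stars = significance_stars([c.p_raw for c in ordered])
    rows = []
    for c, star in zip(ordered, stars):
        rows.append(
            {
                "otu_id": c.otu_id,
                "direction": c.direction,
                "or_c12": c.odds_ratios.or_c12,
                "or_c13": c.odds_ratios.or_c13,
                "bd_statistic": c.bd.statistic,
                "df": c.bd.df,
                "p_value": c.p_raw,
                "holm_rank": c.holm_rank,
                "holm_threshold": c.holm_threshold,
                "significant": c.significant,
                "stars": star,
                "lineage": ";".join(taxonomy.lineage(c.otu_id)),
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return frame
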