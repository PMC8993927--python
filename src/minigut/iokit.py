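"""Shared data model, validation, and TSV readers/writers.

Every pipeline stage exchanges data through the types defined here:
taxon relative-abundance tables, presence/absence matrices, KO profiles,
16S copy-number tables, qPCR totals, and reaction universes. All tabular
formats are plain TSV with a header row; tables default to taxa-as-rows
orientation (the common microbiome-table convention) with a flag to
transpose on read/write.

Validation policy: missing cells are errors, never silently imputed;
identifiers are case-sensitive with whitespace trimmed only at field
edges; every constructor re-checks its type invariants so an accepted
object is always valid.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"^K\d{5}$")

__all__ = [
    "ValidationError",
    "ParseError",
    "TaxonTable",
    "PresenceAbsenceMatrix",
    "KOProfile",
    "CopyNumberTable",
    "QPCRTotals",
    "Reaction",
    "ReactionUniverse",
    "read_taxon_table",
    "write_taxon_table",
    "read_presence_absence",
    "write_presence_absence",
    "read_ko_annotations",
    "read_ko_profile",
    "write_ko_profile",
    "read_copy_numbers",
    "write_copy_numbers",
    "read_qpcr_totals",
    "write_qpcr_totals",
    "read_reaction_universe",
    "write_reaction_universe",
    "read_gmm_definitions",
    "write_run_log",
]


class ValidationError(ValueError):
    """An object or file violates a documented type invariant."""


class ParseError(ValueError):
    """A file cell or token could not be parsed; message names the location."""


# ---------------------------------------------------------------------------
# matrix-backed tables
# ---------------------------------------------------------------------------


def _check_ids(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i).strip() for i in ids)
    if len(ids) == 0:
        raise ValidationError(f"table must have at least one {what}")
    if any(i == "" for i in ids):
        raise ValidationError(f"empty {what} identifier")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")
    return ids


def _check_matrix(values: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValidationError(
            f"value matrix shape {values.shape} does not match "
            f"({n_rows} rows, {n_cols} columns)"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite value in matrix")
    if np.any(values < 0):
        raise ValidationError("negative value in matrix")
    values = values.copy()
    values.flags.writeable = False
    return values


@dataclass(frozen=True)
class TaxonTable:
    """Samples x taxa relative abundances, stored taxa-as-rows.

    Invariants: values >= 0; no duplicated sample or taxon identifiers;
    per-sample sums <= 1 + 1e-9 (tables may be partial).
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_taxa, n_samples)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        object.__setattr__(self, "taxon_ids", _check_ids(self.taxon_ids, "taxon"))
        values = _check_matrix(self.values, len(self.taxon_ids), len(self.sample_ids))
        sums = values.sum(axis=0)
        if np.any(sums > 1.0 + 1e-9):
            bad = [self.sample_ids[j] for j in np.nonzero(sums > 1.0 + 1e-9)[0]]
            raise ValidationError(f"per-sample abundance sums exceed 1: {bad}")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonTable":
        return cls(
            sample_ids=tuple(map(str, df.columns)),
            taxon_ids=tuple(map(str, df.index)),
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Samples x taxa binary matrix, taxa-as-rows; values in {0, 1}."""

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        object.__setattr__(self, "taxon_ids", _check_ids(self.taxon_ids, "taxon"))
        values = _check_matrix(self.values, len(self.taxon_ids), len(self.sample_ids))
        if not np.all(np.isin(values, (0.0, 1.0))):
            raise ValidationError("presence/absence values must be 0 or 1")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def presence_counts(self) -> dict[str, int]:
        return {
            t: int(self.values[i].sum()) for i, t in enumerate(self.taxon_ids)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=list(self.taxon_ids),
            columns=list(self.sample_ids),
        )

    @classmethod
    def from_taxon_table(
        cls, table: TaxonTable, detection: float = 0.0
    ) -> "PresenceAbsenceMatrix":
        """Threshold a relative-abundance table at ``detection`` (inclusive)."""
        if detection < 0:
            raise ValidationError("detection threshold must be >= 0")
        return cls(
            sample_ids=table.sample_ids,
            taxon_ids=table.taxon_ids,
            values=(table.values >= detection).astype(float),
        )


# ---------------------------------------------------------------------------
# KO profiles
# ---------------------------------------------------------------------------

_KO_MODES = ("set", "counts", "cpm")


@dataclass(frozen=True)
class KOProfile:
    """KEGG-ortholog content of one unit (sample, genome, or transcriptome).

    ``kos`` maps KO identifier (``K`` + five digits) to a nonnegative
    abundance. In ``set`` mode all abundances are in {0, 1}; ``counts``
    holds raw counts and ``cpm`` counts-per-million.
    """

    unit_id: str
    kos: Mapping[str, float]
    mode: str = "set"

    def __post_init__(self) -> None:
        if self.mode not in _KO_MODES:
            raise ValidationError(f"mode must be one of {_KO_MODES}, got {self.mode!r}")
        clean: dict[str, float] = {}
        for ko, val in dict(self.kos).items():
            ko = str(ko).strip()
            if not KO_PATTERN.match(ko):
                raise ValidationError(f"malformed KO identifier {ko!r}")
            val = float(val)
            if not np.isfinite(val) or val < 0:
                raise ValidationError(f"abundance of {ko} must be finite and >= 0")
            if self.mode == "set" and val not in (0.0, 1.0):
                raise ValidationError(f"set-mode abundance of {ko} must be 0 or 1")
            clean[ko] = val
        object.__setattr__(self, "kos", clean)

    @classmethod
    def from_set(cls, unit_id: str, kos: Iterable[str]) -> "KOProfile":
        return cls(unit_id=unit_id, kos={k: 1.0 for k in kos}, mode="set")

    def support(self) -> frozenset[str]:
        """KO identifiers with abundance strictly greater than zero."""
        return frozenset(k for k, v in self.kos.items() if v > 0)

    def __len__(self) -> int:
        return len(self.kos)


@dataclass(frozen=True)
class CopyNumberTable:
    """Per-species 16S rRNA gene copy numbers (integers >= 1)."""

    copy_numbers: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sp, cn in dict(self.copy_numbers).items():
            sp = str(sp).strip()
            if float(cn) != int(cn):
                raise ValidationError(f"copy number of {sp!r} must be integer, got {cn}")
            cn = int(cn)
            if cn < 1:
                raise ValidationError(f"copy number of {sp!r} must be >= 1, got {cn}")
            clean[sp] = cn
        object.__setattr__(self, "copy_numbers", clean)

    def __getitem__(self, species: str) -> int:
        return self.copy_numbers[species]

    def __contains__(self, species: str) -> bool:
        return species in self.copy_numbers

    def __iter__(self):
        return iter(self.copy_numbers)


@dataclass(frozen=True)
class QPCRTotals:
    """Per-sample total 16S rRNA gene copies from qPCR.

    When replicate measurements are supplied the stored total is their
    arithmetic mean (the aggregator is a documented design decision; the
    source protocol measured in triplicate without stating one).
    """

    totals: Mapping[str, float]
    replicates: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        totals = {str(k).strip(): float(v) for k, v in dict(self.totals).items()}
        for s, t in totals.items():
            if not np.isfinite(t) or t <= 0:
                raise ValidationError(f"qPCR total for {s!r} must be > 0, got {t}")
        reps = {
            str(k).strip(): tuple(float(x) for x in v)
            for k, v in dict(self.replicates).items()
        }
        for s, vals in reps.items():
            if s not in totals:
                raise ValidationError(f"replicates given for unknown sample {s!r}")
            mean = sum(vals) / len(vals)
            if not np.isclose(mean, totals[s], rtol=1e-9, atol=0.0):
                raise ValidationError(
                    f"stored total for {s!r} ({totals[s]}) is not the mean of "
                    f"its replicates ({mean})"
                )
        object.__setattr__(self, "totals", totals)
        object.__setattr__(self, "replicates", reps)

    @classmethod
    def from_replicates(
        cls, replicates: Mapping[str, Sequence[float]]
    ) -> "QPCRTotals":
        reps = {k: tuple(float(x) for x in v) for k, v in replicates.items()}
        totals = {k: sum(v) / len(v) for k, v in reps.items()}
        return cls(totals=totals, replicates=reps)

    def __getitem__(self, sample: str) -> float:
        return self.totals[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self.totals


# ---------------------------------------------------------------------------
# reaction universe
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    ko_ids: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "ko_ids", frozenset(map(str, self.ko_ids)))
        object.__setattr__(self, "substrates", frozenset(map(str, self.substrates)))
        object.__setattr__(self, "products", frozenset(map(str, self.products)))
        if not self.ko_ids:
            raise ValidationError(f"reaction {self.reaction_id!r} has no KOs")
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id!r} needs >= 1 substrate and product"
            )
        if self.substrates & self.products:
            raise ValidationError(
                f"reaction {self.reaction_id!r} has overlapping substrates/products"
            )
        for ko in self.ko_ids:
            if not KO_PATTERN.match(ko):
                raise ValidationError(
                    f"reaction {self.reaction_id!r}: malformed KO {ko!r}"
                )


@dataclass(frozen=True)
class ReactionUniverse:
    """The KO -> reaction -> compound mapping used to build metabolic networks.

    The universe is an explicit input: no external database snapshot is
    assumed or downloaded.
    """

    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        reactions = tuple(self.reactions)
        ids = [r.reaction_id for r in reactions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate reaction identifiers")
        object.__setattr__(self, "reactions", reactions)

    @property
    def compounds(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.substrates | r.products
        return frozenset(out)

    @property
    def kos(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.ko_ids
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.reactions)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path, taxa_as_rows: bool = True) -> pd.DataFrame:
    # id column set manually: index_col would coerce numeric-looking ids;
    # NA parsing off so "None"/"NA" stay literal and blanks stay detectable
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    df = df.set_index(df.columns[0])
    if not taxa_as_rows:
        df = df.T
    index = [str(i).strip() for i in df.index]
    columns = [str(c).strip() for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ParseError(
                    f"missing value at row {index[i]!r}, column {columns[j]!r}"
                )
            text = str(cell).strip()
            if text == "":
                raise ParseError(
                    f"missing value at row {index[i]!r}, column {columns[j]!r}"
                )
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ParseError(
                    f"malformed numeric cell {text!r} at row {index[i]!r}, "
                    f"column {columns[j]!r}"
                ) from None
    return pd.DataFrame(values, index=index, columns=columns)


def read_taxon_table(path, taxa_as_rows: bool = True) -> TaxonTable:
    """Read a relative-abundance TSV (header row, id column) into a TaxonTable."""
    return TaxonTable.from_frame(_read_matrix_tsv(path, taxa_as_rows))


def write_taxon_table(table: TaxonTable, path, taxa_as_rows: bool = True) -> None:
    df = table.to_frame()
    if not taxa_as_rows:
        df = df.T
    df.to_csv(path, sep="\t", index_label="taxon_id" if taxa_as_rows else "sample_id")


def read_presence_absence(path, taxa_as_rows: bool = True) -> PresenceAbsenceMatrix:
    df = _read_matrix_tsv(path, taxa_as_rows)
    return PresenceAbsenceMatrix(
        sample_ids=tuple(df.columns), taxon_ids=tuple(df.index), values=df.to_numpy()
    )


def write_presence_absence(
    pa: PresenceAbsenceMatrix, path, taxa_as_rows: bool = True
) -> None:
    df = pa.to_frame()
    if not taxa_as_rows:
        df = df.T
    df.to_csv(path, sep="\t", index_label="taxon_id" if taxa_as_rows else "sample_id")


def read_ko_annotations(path, unit_id: str | None = None) -> KOProfile:
    """Read a two-column ``locus_tag<TAB>KO`` annotation file into a set-mode profile.

    Loci with an empty KO field (unannotated) are dropped; the number of
    dropped loci is logged. A KO token not matching ``K#####`` raises a
    :class:`ParseError` naming the line.
    """
    kos: set[str] = set()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            parts = line.split("\t")
            ko = parts[1].strip() if len(parts) > 1 else ""
            if ko == "":
                dropped += 1
                continue
            if not KO_PATTERN.match(ko):
                raise ParseError(f"line {lineno}: malformed KO token {ko!r}")
            kos.add(ko)
    if dropped:
        logger.info("read_ko_annotations(%s): dropped %d unannotated loci", path, dropped)
    uid = unit_id if unit_id is not None else str(path)
    return KOProfile.from_set(uid, kos)


def read_ko_profile(path, unit_id: str | None = None, mode: str = "counts") -> KOProfile:
    """Read a two-column ``KO<TAB>abundance`` TSV (no header)."""
    kos: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected KO<TAB>abundance")
            ko = parts[0].strip()
            try:
                val = float(parts[1].strip())
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed abundance {parts[1]!r}"
                ) from None
            if ko in kos:
                raise ValidationError(f"line {lineno}: duplicate KO {ko!r}")
            kos[ko] = val
    uid = unit_id if unit_id is not None else str(path)
    return KOProfile(unit_id=uid, kos=kos, mode=mode)


def write_ko_profile(profile: KOProfile, path) -> None:
    with open(path, "w") as fh:
        for ko in sorted(profile.kos):
            fh.write(f"{ko}\t{profile.kos[ko]!r}\n")


def read_copy_numbers(path) -> CopyNumberTable:
    """Read a headered ``species_id<TAB>copy_number`` TSV."""
    cns: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() == "":
            raise ParseError("empty copy-number file")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected species_id<TAB>copy_number")
            sp = parts[0].strip()
            if sp in cns:
                raise ValidationError(f"line {lineno}: duplicate species {sp!r}")
            try:
                cns[sp] = int(parts[1].strip())
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed copy number {parts[1]!r}"
                ) from None
    return CopyNumberTable(cns)


def write_copy_numbers(cn: CopyNumberTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tcopy_number\n")
        for sp, v in cn.copy_numbers.items():
            fh.write(f"{sp}\t{v}\n")


def read_qpcr_totals(path) -> QPCRTotals:
    """Read qPCR totals: header then ``sample_id`` plus one or more value columns.

    With a single value column the value is the total; with several, the
    columns are replicate measurements and the total is their mean.
    """
    reps: dict[str, tuple[float, ...]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() == "":
            raise ParseError("empty qPCR file")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected sample_id and >=1 value")
            sample = parts[0].strip()
            if sample in reps:
                raise ValidationError(f"line {lineno}: duplicate sample {sample!r}")
            try:
                vals = tuple(float(p.strip()) for p in parts[1:] if p.strip() != "")
            except ValueError:
                raise ParseError(f"line {lineno}: malformed qPCR value") from None
            if not vals:
                raise ParseError(f"line {lineno}: no qPCR values for {sample!r}")
            reps[sample] = vals
    return QPCRTotals.from_replicates(reps)


def write_qpcr_totals(totals: QPCRTotals, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttotal_16s_copies\n")
        for s, t in totals.totals.items():
            fh.write(f"{s}\t{t!r}\n")


_UNIVERSE_COLUMNS = ["reaction_id", "kos", "substrates", "products", "reversible"]


def read_reaction_universe(path) -> ReactionUniverse:
    """Read a reaction-universe TSV (semicolon-joined KO/compound fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _UNIVERSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"reaction universe missing columns: {missing}")
    reactions = []
    for _, row in df.iterrows():
        rev_token = str(row["reversible"]).strip()
        if rev_token not in ("0", "1"):
            raise ParseError(
                f"reaction {row['reaction_id']!r}: reversible must be 0/1, "
                f"got {rev_token!r}"
            )
        reactions.append(
            Reaction(
                reaction_id=str(row["reaction_id"]).strip(),
                ko_ids=frozenset(
                    t.strip() for t in str(row["kos"]).split(";") if t.strip()
                ),
                substrates=frozenset(
                    t.strip() for t in str(row["substrates"]).split(";") if t.strip()
                ),
                products=frozenset(
                    t.strip() for t in str(row["products"]).split(";") if t.strip()
                ),
                reversible=rev_token == "1",
            )
        )
    return ReactionUniverse(tuple(reactions))


def write_reaction_universe(universe: ReactionUniverse, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_UNIVERSE_COLUMNS) + "\n")
        for r in universe.reactions:
            fh.write(
                "\t".join(
                    [
                        r.reaction_id,
                        ";".join(sorted(r.ko_ids)),
                        ";".join(sorted(r.substrates)),
                        ";".join(sorted(r.products)),
                        "1" if r.reversible else "0",
                    ]
                )
                + "\n"
            )


def read_gmm_definitions(path):
    """Read gut-metabolic-module definitions (dialect documented in gmmscore)."""
    from . import gmmscore

    return gmmscore.read_gmm_definitions(path)


def write_run_log(path, params: Mapping) -> None:
    """Echo run parameters to a YAML log so every result records its settings."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(params), fh, sort_keys=True)
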