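"""Vocabularies, the 6ddp data model, and tabular readers/writers.

A 6ddp ("6-dimensional data point") describes one non-synonymous SNV by six
discrete variables: the protein functional domain it falls in (``cd``), the
pooled residue substitution (``re``), the contributing human population
(``po``), the binned allele frequency (``af``), and the two outcome variables
phenotype (``ph``) and pathogenicity (``pa``).  A record is *fulfilled* when
both outcomes are known.

The canonical on-disk format is delimited text (CSV, UTF-8, header row) with
columns ``cd,re_ref,re_sub,po,af_cat,ph,pa``; an xlsx reader is provided for
convenience with the original supplementary spreadsheets, but CSV is the
tested dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "VocabularyError",
    "PATHOGENICITY_CODES",
    "UNKNOWN_PATHOGENICITY",
    "UNKNOWN_PHENOTYPE",
    "AMINO_ALPHABET",
    "POOLING_MAP",
    "POOLED_CLASSES",
    "PooledSubstitution",
    "DomainEntry",
    "DomainVocabulary",
    "CodeVocabulary",
    "SixDDPRecord",
    "SixDDPDataset",
    "pool_substitution",
    "bin_allele_frequency",
    "resolve_annotations",
    "load_6ddp",
    "write_6ddp",
    "load_vocabularies",
]


class VocabularyError(ValueError):
    """A code, letter, or table violates its vocabulary contract."""


# ---------------------------------------------------------------------------
# Pathogenicity / phenotype code sets
# ---------------------------------------------------------------------------

#: The five pathogenicity classes: pathogenic, likely pathogenic, benign,
#: likely benign, unknown.
PATHOGENICITY_CODES: tuple[str, ...] = ("pt", "lp", "be", "lb", "uk")
UNKNOWN_PATHOGENICITY = "uk"
#: Phenotype vocabularies must contain this code for "unknown phenotype".
UNKNOWN_PHENOTYPE = "uk"

PATHOGENIC_CLASSES: tuple[str, ...] = ("lp", "pt")
BENIGN_CLASSES: tuple[str, ...] = ("lb", "be")


# ---------------------------------------------------------------------------
# Residue-substitution pooling
# ---------------------------------------------------------------------------

#: 20 standard amino acids (one-letter) plus the stop/termination symbol.
AMINO_ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)

#: Pooling by size, hydrophilicity and charge: Arg,His -> Lys; Asp -> Glu;
#: Ser -> Thr; Asn -> Gln; Ala,Val,Ile,Met,Phe,Trp -> Leu.  Letters not named
#: are their own class, giving a 10-class pooled alphabet.
POOLING_MAP: dict[str, str] = {
    "R": "K", "H": "K",
    "D": "E",
    "S": "T",
    "N": "Q",
    "A": "L", "V": "L", "I": "L", "M": "L", "F": "L", "W": "L",
}

POOLED_CLASSES: tuple[str, ...] = tuple(
    sorted({POOLING_MAP.get(a, a) for a in AMINO_ALPHABET})
)

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Stop": "*",
}


def _normalize_letter(aa: str) -> str:
    """Accept one-letter or three-letter amino-acid names; return one-letter."""
    if aa in _THREE_TO_ONE:
        aa = _THREE_TO_ONE[aa]
    elif len(aa) == 3 and aa.capitalize() in _THREE_TO_ONE:
        aa = _THREE_TO_ONE[aa.capitalize()]
    if aa not in AMINO_ALPHABET:
        raise VocabularyError(f"unknown amino-acid letter {aa!r}")
    return aa


@dataclass(frozen=True)
class PooledSubstitution:
    """A reference/substituted residue pair after pooling."""

    ref_class: str
    sub_class: str

    def __post_init__(self) -> None:
        for c in (self.ref_class, self.sub_class):
            if c not in POOLED_CLASSES:
                raise VocabularyError(f"{c!r} is not a pooled residue class")


def pool_substitution(ref: str, sub: str) -> PooledSubstitution:
    """Map a raw reference/substituted residue pair to its pooled classes.

    Accepts one-letter or three-letter names, including the stop symbol
    (``*`` / ``Ter``).  Idempotent on its own outputs: pooled classes map to
    themselves.
    """
    r = _normalize_letter(ref)
    s = _normalize_letter(sub)
    return PooledSubstitution(POOLING_MAP.get(r, r), POOLING_MAP.get(s, s))


def bin_allele_frequency(af: float) -> int:
    """Bin a fractional allele frequency into category 0 (<=1%) or 1 (>1%)."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return 0 if af <= 0.01 else 1


def resolve_annotations(
    submissions: Sequence[tuple[str, str]],
    unknown_ph: str = UNKNOWN_PHENOTYPE,
    unknown_pa: str = UNKNOWN_PATHOGENICITY,
) -> tuple[str, str]:
    """Collapse multiple provider (phenotype, pathogenicity) annotations.

    Each outcome resolves independently to the strict-majority code (more than
    half the submissions); any tie or plurality-without-majority yields the
    unknown code.
    """
    if not submissions:
        raise ValueError("no provider submissions to resolve")

    def majority(values: list[str], unknown: str) -> str:
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts, key=lambda c: counts[c])
        return best if counts[best] * 2 > len(values) else unknown

    return (
        majority([ph for ph, _ in submissions], unknown_ph),
        majority([pa for _, pa in submissions], unknown_pa),
    )


# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

_KNOWN_PROTEINS = ("MYH7-heavy-chain", "MYL2", "MYL3", "MYBPC3", "MAPT")


@dataclass(frozen=True)
class DomainEntry:
    index: int
    code: str
    protein: str
    residue_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise VocabularyError(f"domain index {self.index} must be >= 1")
        if len(self.code) != 2:
            raise VocabularyError(f"domain code {self.code!r} is not 2 letters")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo < 1 or hi < lo:
                raise VocabularyError(
                    f"bad residue range {self.residue_range} for {self.code}"
                )


@dataclass(frozen=True)
class DomainVocabulary:
    """Ordered protein functional domains with 1-based contiguous indices.

    In a two-protein complex map the first protein's domains occupy the low
    index block (e.g. the heavy-chain motor complex at 1..39) and the partner
    the remainder (e.g. MYBPC3 at 40..65); ``block_boundary`` is the last
    index of the first block.
    """

    entries: tuple[DomainEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise VocabularyError("domain vocabulary is empty")
        indices = [e.index for e in self.entries]
        if indices != list(range(1, len(indices) + 1)):
            raise VocabularyError(
                "domain indices must be consecutive from 1 with no gaps; "
                f"got {indices[:8]}..."
            )
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise VocabularyError(f"duplicate domain codes {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self._index_map()

    def _index_map(self) -> dict[str, int]:
        return {e.code: e.index for e in self.entries}

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    def index_of(self, code: str) -> int:
        try:
            return self._index_map()[code]
        except KeyError:
            raise VocabularyError(f"unknown domain code {code!r}") from None

    def code_at(self, index: int) -> str:
        return self.entries[index - 1].code

    @property
    def proteins(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.protein not in seen:
                seen.append(e.protein)
        return tuple(seen)

    def protein_block(self, protein: str) -> tuple[int, int]:
        """Inclusive (first, last) index span of one protein's domains."""
        idx = [e.index for e in self.entries if e.protein == protein]
        if not idx:
            raise VocabularyError(f"no domains for protein {protein!r}")
        return (min(idx), max(idx))

    @property
    def block_boundary(self) -> int:
        """Last index of the first protein block (39 for the 65-domain
        heavy-chain/MYBPC3 map, so the boundary sits between 39 and 40)."""
        first = self.entries[0].protein
        # light chains belong to the same molecular complex block as the
        # heavy chain: the boundary is where the *partner* protein starts
        partner = self.entries[-1].protein
        start, _ = self.protein_block(partner)
        if start == 1:
            raise VocabularyError("single-protein vocabulary has no boundary")
        del first
        return start - 1


@dataclass(frozen=True)
class CodeVocabulary:
    """A flat code -> name vocabulary (populations, phenotypes)."""

    entries: tuple[tuple[str, str], ...]
    code_length: int = 3

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise VocabularyError(f"duplicate codes {dupes}")
        for c in codes:
            if len(c) != self.code_length:
                raise VocabularyError(
                    f"code {c!r} is not {self.code_length} characters"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return any(c == code for c, _ in self.entries)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)


# ---------------------------------------------------------------------------
# 6ddp records and datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SixDDPRecord:
    """One SNV variation: (cd, re, po, af, ph, pa)."""

    cd: str
    re: PooledSubstitution
    po: str
    af: int
    ph: str
    pa: str

    def __post_init__(self) -> None:
        if self.af not in (0, 1):
            raise VocabularyError(f"allele-frequency category {self.af!r} not in {{0,1}}")
        if self.pa not in PATHOGENICITY_CODES:
            raise VocabularyError(f"pathogenicity code {self.pa!r} invalid")

    @property
    def fulfilled(self) -> bool:
        return self.ph != UNKNOWN_PHENOTYPE and self.pa != UNKNOWN_PATHOGENICITY

    def validate(self, domains: DomainVocabulary, populations: CodeVocabulary,
                 phenotypes: CodeVocabulary) -> None:
        if self.cd not in domains:
            raise VocabularyError(f"unknown domain code {self.cd!r}")
        if self.po not in populations:
            raise VocabularyError(f"unknown population code {self.po!r}")
        if self.ph not in phenotypes and self.ph != UNKNOWN_PHENOTYPE:
            raise VocabularyError(f"unknown phenotype code {self.ph!r}")


@dataclass
class SixDDPDataset:
    records: list[SixDDPRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def fulfilled_mask(self) -> list[bool]:
        return [r.fulfilled for r in self.records]

    @property
    def n_fulfilled(self) -> int:
        return sum(self.fulfilled_mask)

    def fulfilled(self) -> "SixDDPDataset":
        return SixDDPDataset([r for r in self.records if r.fulfilled],
                             provenance=self.provenance)

    def unfulfilled(self) -> "SixDDPDataset":
        return SixDDPDataset([r for r in self.records if not r.fulfilled],
                             provenance=self.provenance)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

SIXDDP_COLUMNS = ("cd", "re_ref", "re_sub", "po", "af_cat", "ph", "pa")


def _records_from_rows(
    rows: Iterable[dict],
    domains: DomainVocabulary,
    populations: CodeVocabulary,
    phenotypes: CodeVocabulary,
) -> list[SixDDPRecord]:
    records = []
    for lineno, row in enumerate(rows, start=2):  # header is line 1
        try:
            re_pair = PooledSubstitution(str(row["re_ref"]), str(row["re_sub"]))
            rec = SixDDPRecord(
                cd=str(row["cd"]),
                re=re_pair,
                po=str(row["po"]),
                af=int(row["af_cat"]),
                ph=str(row["ph"]),
                pa=str(row["pa"]),
            )
            rec.validate(domains, populations, phenotypes)
        except (VocabularyError, KeyError, TypeError) as exc:
            raise VocabularyError(f"row {lineno}: {exc}") from exc
        except ValueError as exc:
            raise VocabularyError(f"row {lineno}: malformed value ({exc})") from exc
        records.append(rec)
    return records


def load_6ddp(
    path: str | Path,
    domains: DomainVocabulary,
    populations: CodeVocabulary,
    phenotypes: CodeVocabulary,
) -> SixDDPDataset:
    """Read a 6ddp table (CSV, or xlsx for the supplementary spreadsheets)."""
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        import pandas as pd

        frame = pd.read_excel(path)
        missing = set(SIXDDP_COLUMNS) - set(frame.columns)
        if missing:
            raise VocabularyError(f"{path.name}: missing columns {sorted(missing)}")
        rows: Iterable[dict] = frame.to_dict("records")
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(SIXDDP_COLUMNS) - set(reader.fieldnames):
                raise VocabularyError(
                    f"{path.name}: header must name columns {SIXDDP_COLUMNS}"
                )
            rows = list(reader)
    records = _records_from_rows(rows, domains, populations, phenotypes)
    return SixDDPDataset(records, provenance=path.name)


def write_6ddp(dataset: SixDDPDataset, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIXDDP_COLUMNS)
        for r in dataset.records:
            writer.writerow(
                [r.cd, r.re.ref_class, r.re.sub_class, r.po, r.af, r.ph, r.pa]
            )


def _read_csv_rows(path: Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_vocabularies(
    domain_path: str | Path,
    population_path: str | Path,
    phenotype_path: str | Path,
) -> tuple[DomainVocabulary, CodeVocabulary, CodeVocabulary]:
    """Read the three vocabulary CSVs.

    Domain schema: ``index,code,protein,res_start,res_end`` (range optional);
    population and phenotype schema: ``code,name``.
    """
    dom_rows = _read_csv_rows(Path(domain_path))
    entries = []
    for row in dom_rows:
        rng = None
        if row.get("res_start") and row.get("res_end"):
            rng = (int(row["res_start"]), int(row["res_end"]))
        protein = row["protein"]
        if protein not in _KNOWN_PROTEINS:
            # accept novel proteins but keep the canonical five recognizable
            protein = str(protein)
        entries.append(
            DomainEntry(int(row["index"]), row["code"], protein, rng)
        )
    entries.sort(key=lambda e: e.index)
    domains = DomainVocabulary(tuple(entries))

    def code_vocab(path: Path, length: int) -> CodeVocabulary:
        rows = _read_csv_rows(path)
        return CodeVocabulary(
            tuple((row["code"], row.get("name", "")) for row in rows),
            code_length=length,
        )

    populations = code_vocab(Path(population_path), 3)
    phenotypes = code_vocab(Path(phenotype_path), 2)
    return domains, populations, phenotypes
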