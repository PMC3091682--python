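"""Integration of multiple miRNA target-prediction catalogs.

Each catalog is a set of (mirna_id, gene_id) pairs. A validation database
(TarBase-style) is filtered to support types "True" or "Microarray" on
ingest. miRNA symbols that do not match the reference id set are rescued
by trying numeric suffix extensions ("-1".."-5", all matches kept) and,
failing that, stripping a single trailing letter and retrying; symbols
with no match are dropped. The *prediction agreement* of a pair is the
number of distinct sources containing it, used downstream as a confidence
proxy (>= 6 of the seven sources defines the high-confidence set, >= 2 the
coverage set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT_FILTER = frozenset({"True", "Microarray"})
MAX_NUMERIC_SUFFIX = 5

Pair = tuple[str, str]


@dataclass(frozen=True)
class PredictionSource:
    name: str
    pairs: frozenset[Pair]
    is_validation_db: bool = False


def read_prediction_table(
    path: str | Path,
    name: str,
    is_validation_db: bool = False,
    support_filter: frozenset[str] | None = None,
) -> PredictionSource:
    """Read a TSV with columns ``mirna``, ``gene`` (+ optional ``support``).

    For a validation database only rows whose support label is admissible
    (default {"True", "Microarray"}) are retained.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if is_validation_db:
        admissible = support_filter or DEFAULT_SUPPORT_FILTER
        if "support" not in df.columns:
            raise ValueError(f"{path}: validation database lacks 'support' column")
        df = df[df["support"].isin(admissible)]
    pairs = frozenset(zip(df["mirna"], df["gene"]))
    if not pairs:
        logger.warning("%s: no prediction pairs after filtering", path)
    return PredictionSource(name=name, pairs=pairs, is_validation_db=is_validation_db)


def harmonize_mirna_id(symbol: str, known_symbols: Iterable[str]) -> set[str]:
    """Match a catalog miRNA symbol against the reference symbol set.

    Exact match wins; otherwise numeric-suffix extensions "-1".."-5" (all
    matches returned); otherwise a single trailing letter is stripped and
    the exact/suffix search repeated. An empty set means: ignore this
    symbol's predictions.
    """
    known = set(known_symbols)
    if not known:
        raise ValueError("known_symbols must be non-empty")

    def trials(base: str) -> set[str]:
        if base in known:
            return {base}
        hits = {
            cand
            for i in range(1, MAX_NUMERIC_SUFFIX + 1)
            if (cand := f"{base}-{i}") in known
        }
        return hits

    hits = trials(symbol)
    if hits:
        return hits
    if symbol and symbol[-1].isalpha():
        return trials(symbol[:-1])
    return set()


def harmonize_source(
    source: PredictionSource, known_symbols: Iterable[str]
) -> PredictionSource:
    """Remap every pair's miRNA symbol onto the reference set."""
    known = set(known_symbols)
    cache: dict[str, set[str]] = {}
    pairs: set[Pair] = set()
    dropped = 0
    for mirna, gene in source.pairs:
        if mirna not in cache:
            cache[mirna] = harmonize_mirna_id(mirna, known)
        matches = cache[mirna]
        if not matches:
            dropped += 1
            continue
        pairs.update((m, gene) for m in matches)
    if dropped:
        logger.info("%s: %d pairs dropped (unmatched miRNA symbols)",
                    source.name, dropped)
    return PredictionSource(source.name, frozenset(pairs), source.is_validation_db)


@dataclass
class AgreementMatrix:
    """(miRNA, gene) → number of distinct sources supporting the pair."""

    counts: dict[Pair, int]
    n_sources: int
    source_names: tuple[str, ...] = ()
    membership: dict[str, frozenset[Pair]] = field(default_factory=dict)

    def agreement(self, mirna: str, gene: str) -> int:
        return self.counts.get((mirna, gene), 0)


def build_agreement(sources: Sequence[PredictionSource]) -> AgreementMatrix:
    """Count, per pair, the distinct sources containing it."""
    if not sources:
        raise ValueError("need at least one prediction source")
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate source names in {names}")
    counts: dict[Pair, int] = {}
    for src in sources:
        for pair in src.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    return AgreementMatrix(
        counts=counts,
        n_sources=len(sources),
        source_names=tuple(names),
        membership={s.name: s.pairs for s in sources},
    )


def high_confidence(matrix: AgreementMatrix, k: int) -> set[Pair]:
    """Pairs supported by at least ``k`` sources."""
    if not (1 <= k <= matrix.n_sources):
        raise ValueError(f"k={k} out of range 1..{matrix.n_sources}")
    return {pair for pair, c in matrix.counts.items() if c >= k}


@dataclass(frozen=True)
class VotingGroups:
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.group_a & self.group_b:
            raise ValueError("voting groups must be disjoint")


def group_vote(
    sources: Sequence[PredictionSource], groups: VotingGroups, pair: Pair
) -> bool:
    """True iff at least one source of each voting group contains the pair."""
    by_name: Mapping[str, PredictionSource] = {s.name: s for s in sources}
    for name in groups.group_a | groups.group_b:
        if name not in by_name:
            raise ValueError(f"unknown source name {name!r}")
        if by_name[name].is_validation_db:
            raise ValueError(f"validation database {name!r} cannot vote")
    in_a = any(pair in by_name[n].pairs for n in groups.group_a)
    in_b = any(pair in by_name[n].pairs for n in groups.group_b)
    return in_a and in_b


def agreement_frame(matrix: AgreementMatrix) -> pd.DataFrame:
    """One row per pair: agreement count plus per-source membership flags."""
    rows = []
    for (mirna, gene), c in sorted(matrix.counts.items()):
        row = {"mirna": mirna, "gene": gene, "agreement": c}
        for name in matrix.source_names:
            row[name] = (mirna, gene) in matrix.membership.get(name, frozenset())
        rows.append(row)
    return pd.DataFrame(rows)
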