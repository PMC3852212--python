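"""miRNA -> target-gene relation tables.

A target map is a many-to-many relation between miRNAs and the genes they
repress, aggregated from several prediction programs; each pair carries a
vote count (the number of programs predicting it, 1..11). Filtering on the
vote count trades coverage against confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, EmptyTargetMapError, ParseError

logger = logging.getLogger(__name__)

MAX_VOTES = 11  # number of upstream prediction programs

__all__ = ["TargetMap", "read_target_map", "filter_by_votes", "write_target_map"]


@dataclass(frozen=True)
class TargetMap:
    """A set of (mirna_id, gene_id) pairs with integer vote counts.

    ``mirna_index`` / ``gene_index`` resolve each ID to its column in the
    corresponding expression matrix; pairs are only kept when both ends are
    measured features.
    """

    pairs: tuple[tuple[str, str, int], ...]
    mirna_index: dict[str, int]
    gene_index: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for mirna, gene, votes in self.pairs:
            key = (mirna, gene)
            if key in seen:
                raise ConfigurationError(f"duplicate target pair {key}")
            seen.add(key)
            if votes < 1:
                raise ConfigurationError(f"pair {key} has votes={votes} < 1")
            if mirna not in self.mirna_index:
                raise ConfigurationError(f"miRNA {mirna!r} missing from mirna_index")
            if gene not in self.gene_index:
                raise ConfigurationError(f"gene {gene!r} missing from gene_index")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mirna_ids(self) -> set[str]:
        return {m for m, _, _ in self.pairs}

    @property
    def gene_ids(self) -> set[str]:
        return {g for _, g, _ in self.pairs}

    def index_pairs(self) -> list[tuple[int, int]]:
        """(miRNA column, gene column) index pairs for matrix arithmetic."""
        return [(self.mirna_index[m], self.gene_index[g]) for m, g, _ in self.pairs]


def read_target_map(path, mirna_features, gene_features) -> TargetMap:
    """Read a targets.tsv table and resolve IDs against the feature lists.

    Accepts the 3-column ``mirna_id, gene_id, votes`` format and a 2-column
    dialect without votes, treated as the maximal vote count. Pairs whose
    miRNA or gene is not a measured feature are dropped with a logged count;
    duplicate pairs (same miRNA and gene) are an error.
    """
    mirna_index = {str(f): i for i, f in enumerate(mirna_features)}
    gene_index = {str(f): i for i, f in enumerate(gene_features)}

    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        header = fh.readline()
        if header == "":
            raise ParseError(f"{path}: empty file")
        n_cols = len(header.rstrip("\n").split("\t"))
        if n_cols not in (2, 3):
            raise ParseError(f"{path}: line 1: expected 2 or 3 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ParseError(f"{path}: line {lineno}: expected {n_cols} columns")
            if n_cols == 3:
                try:
                    votes = int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: votes not an integer") from exc
            else:
                votes = MAX_VOTES
            rows.append((fields[0], fields[1], votes))

    seen: dict[tuple[str, str], int] = {}
    kept: list[tuple[str, str, int]] = []
    dropped = 0
    for mirna, gene, votes in rows:
        if mirna not in mirna_index or gene not in gene_index:
            dropped += 1
            continue
        key = (mirna, gene)
        if key in seen:
            raise ParseError(f"duplicate target pair {key} with votes {seen[key]} and {votes}")
        seen[key] = votes
        kept.append((mirna, gene, votes))
    if dropped:
        logger.warning("dropped %d target pairs referencing unmeasured features", dropped)
    if not kept:
        raise EmptyTargetMapError(f"{path}: no usable target pairs after ID resolution")
    return TargetMap(tuple(kept), mirna_index, gene_index)


def filter_by_votes(target_map: TargetMap, min_votes: int) -> TargetMap:
    """Keep exactly the pairs with ``votes >= min_votes``; returns a new map."""
    if not 1 <= min_votes <= MAX_VOTES + 1:
        raise ConfigurationError(f"min_votes={min_votes} outside [1, {MAX_VOTES + 1}]")
    kept = tuple(p for p in target_map.pairs if p[2] >= min_votes)
    return TargetMap(kept, target_map.mirna_index, target_map.gene_index)


def write_target_map(target_map: TargetMap, path) -> None:
    pd.DataFrame(list(target_map.pairs), columns=["mirna_id", "gene_id", "votes"]).to_csv(
        path, sep="\t", index=False
    )
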