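"""Ortholog gene-family tables: parsing, category and missing-family accounting.

Gene families come from Markov-clustering style orthology output in the
classic groups dialect (``FAM0001: spA|g1 spB|g2 ...``).  Against a
declared species universe and per-species gene universes, every annotated
gene falls into exactly one of five categories:

* **single-copy core** — family with exactly one gene in every species;
* **variable-copy core** — family with >=1 gene in every species and more
  than one somewhere;
* **dispensable** — family present in at least two but not all species;
* **species-specific cluster** — family whose >=2 genes all come from one
  species;
* **singleton** — an annotated gene assigned to no family at all.

A family is *missing* for a species when that species is the only one
without a representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = (
    "single_copy_core",
    "variable_copy_core",
    "dispensable",
    "species_specific",
    "singleton",
)


@dataclass
class ClusterTable:
    """family_id -> {species -> [gene ids]} plus the declared universes."""

    families: dict
    species: tuple
    gene_universes: dict  # species -> set of all annotated gene ids

    def __post_init__(self):
        self.species = tuple(self.species)
        seen = {}
        for fam, by_sp in self.families.items():
            for sp, genes in by_sp.items():
                if sp not in self.species:
                    raise ValueError(f"family {fam}: unknown species {sp!r}")
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} in both {seen[g]} and {fam}"
                        )
                    seen[g] = fam
                    if g not in self.gene_universes.get(sp, ()):
                        raise ValueError(
                            f"family {fam}: gene {g!r} not in {sp} universe"
                        )

    def unclustered(self, species: str) -> set:
        clustered = {
            g
            for by_sp in self.families.values()
            for g in by_sp.get(species, ())
        }
        return set(self.gene_universes[species]) - clustered


def read_groups(path, species_universe, gene_universes) -> ClusterTable:
    """Parse a groups file (``ID: sp|gene sp|gene ...``) into a ClusterTable.

    A gene appearing in two families, or a species prefix outside the
    declared universe, is a hard error naming the offending line.
    """
    species_universe = tuple(species_universe)
    families = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                fam, rest = line.split(":", 1)
            except ValueError:
                raise ValueError(f"line {lineno}: expected 'FAMILY: members'")
            fam = fam.strip()
            if fam in families:
                raise ValueError(f"line {lineno}: duplicate family {fam!r}")
            by_sp = {}
            for token in rest.split():
                try:
                    sp, gene = token.split("|", 1)
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: member {token!r} not 'species|gene'"
                    )
                if sp not in species_universe:
                    raise ValueError(
                        f"line {lineno}: unknown species prefix {sp!r}"
                    )
                by_sp.setdefault(sp, []).append(gene)
            families[fam] = by_sp
    return ClusterTable(families, species_universe, gene_universes)


def write_groups(table: ClusterTable, path) -> None:
    with open(path, "w") as fh:
        for fam in sorted(table.families):
            members = [
                f"{sp}|{g}"
                for sp in table.species
                for g in table.families[fam].get(sp, ())
            ]
            fh.write(f"{fam}: {' '.join(members)}\n")


def family_category(by_sp: dict, species) -> str:
    """Category of one family given the species universe (no singletons here)."""
    present = [sp for sp in species if by_sp.get(sp)]
    n_present = len(present)
    if n_present == len(species):
        if all(len(by_sp[sp]) == 1 for sp in species):
            return "single_copy_core"
        return "variable_copy_core"
    if n_present == 1:
        return "species_specific"
    return "dispensable"


def classify_genes(table: ClusterTable):
    """Per-gene category assignment plus the per-species category counts.

    Returns ``(assignment, counts)``: a DataFrame with one row per
    annotated gene (``gene_id, species, family_id, category``) and a
    species x category count table.  Categories partition every gene of
    every declared gene universe.
    """
    rows = []
    for fam, by_sp in table.families.items():
        cat = family_category(by_sp, table.species)
        for sp in table.species:
            for g in by_sp.get(sp, ()):
                rows.append((g, sp, fam, cat))
    for sp in table.species:
        for g in sorted(table.unclustered(sp)):
            rows.append((g, sp, None, "singleton"))
    assignment = pd.DataFrame(
        rows, columns=["gene_id", "species", "family_id", "category"]
    )
    counts = (
        assignment.pivot_table(
            index="species",
            columns="category",
            values="gene_id",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(index=list(table.species), columns=list(CATEGORIES), fill_value=0)
        .astype(int)
    )
    return assignment, counts


def missing_families(table: ClusterTable) -> pd.Series:
    """Per-species count of families absent from that species alone."""
    counts = {sp: 0 for sp in table.species}
    for by_sp in table.families.values():
        absent = [sp for sp in table.species if not by_sp.get(sp)]
        if len(absent) == 1:
            counts[absent[0]] += 1
    return pd.Series(counts, name="missing_families")


def family_terms(member_term_sets, threshold: float = 0.40) -> set:
    """Terms carried by at least ``threshold`` of a family's member genes.

    The boundary is inclusive: with 10 members a term on exactly 4 genes
    is kept at the default 40% threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    members = list(member_term_sets)
    if not members:
        raise ValueError("empty family")
    n = len(members)
    tally = {}
    for terms in members:
        for t in set(terms):
            tally[t] = tally.get(t, 0) + 1
    return {t for t, c in tally.items() if c / n >= threshold}
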