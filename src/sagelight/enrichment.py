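"""Protein-domain enrichment of DEG sets and lineage-specificity calls.

Domain enrichment compares, for each conserved domain, the number of
domain-bearing ORFs inside a DEG set against the whole ORF universe with a
one-sided (over-representation) Fisher exact test; a domain is enriched at
p < 0.05. Assignments are pre-filtered at e < 1e-20, the threshold at which
the domain tables were built.

Lineage classification consumes per-species best-hit e-values from tabular
homology-search reports (12-column BLAST outfmt-6 dialect). A DEG counts as
unique to fruiting-body-forming basidiomycetes when it has a homolog
(e < 1e-10) in at least two of the fruiting-body-forming species and no hit
at even moderate similarity (e <= 1e-2) in any outgroup; it counts as
species-unique when no species at all yields a hit below 1e-10.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from scipy import stats as sps

DOMAIN_EVALUE_MAX = 1e-20
HOMOLOGY_EVALUE = 1e-10
DISSIMILARITY_EVALUE = 1e-2

BASIDIOMYCETE_UNIQUE = "basidiomycete_unique"
SPECIES_UNIQUE = "species_unique"
NEITHER = "neither"


@dataclass(frozen=True)
class DomainAssignment:
    orf_id: str
    domain_id: str
    e_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    domain_id: str
    k_deg: int    # DEG ORFs carrying the domain
    n_deg: int    # DEG set size
    k_all: int    # ORFs in the universe carrying the domain
    n_all: int    # universe size
    p_value: float
    enriched: bool


@dataclass(frozen=True)
class LineageCall:
    gene_id: str
    best_e_values: Mapping[str, float]  # species -> best hit e-value
    classification: str


def filter_assignments(
    assignments: Iterable[DomainAssignment],
    e_max: float = DOMAIN_EVALUE_MAX,
) -> List[DomainAssignment]:
    return [a for a in assignments if a.e_value < e_max]


def domain_enrichment(
    assignments: Sequence[DomainAssignment],
    deg_set: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    e_max: float = DOMAIN_EVALUE_MAX,
) -> List[EnrichmentResult]:
    """One-sided Fisher enrichment of each domain in ``deg_set`` vs the ORF
    universe. Domain presence is counted at the ORF level (an ORF carrying a
    domain twice counts once)."""
    deg = set(deg_set)
    uni = set(universe)
    stray = deg - uni
    if stray:
        raise ValueError(f"DEG genes absent from universe: {sorted(stray)}")
    carriers: Dict[str, Set[str]] = defaultdict(set)
    for a in filter_assignments(assignments, e_max):
        if a.orf_id in uni:
            carriers[a.domain_id].add(a.orf_id)
    n_all, n_deg = len(uni), len(deg)
    results = []
    for domain_id in sorted(carriers):
        orfs = carriers[domain_id]
        k_all = len(orfs)
        k_deg = len(orfs & deg)
        # P(X >= k_deg) for X ~ Hypergeom(N=n_all, K=k_all, n=n_deg)
        p = float(sps.hypergeom.sf(k_deg - 1, n_all, k_all, n_deg))
        p = min(p, 1.0)
        results.append(EnrichmentResult(
            domain_id=domain_id, k_deg=k_deg, n_deg=n_deg,
            k_all=k_all, n_all=n_all, p_value=p, enriched=p < alpha))
    return results


# ---------------------------------------------------------------------------
# lineage classification

def read_blast_tabular(path) -> Dict[str, float]:
    """Best (lowest) e-value per query from a 12-column tabular homology
    report (query, subject, identity, length, mismatches, gaps, qstart,
    qend, sstart, send, e-value, bitscore)."""
    best: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                query, e_value = fields[0], float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad e-value field") from exc
            if query not in best or e_value < best[query]:
                best[query] = e_value
    return best


def classify_lineage(
    gene_id: str,
    best_e_values: Mapping[str, float],
    fruiting_body_species: Iterable[str],
    homology_e: float = HOMOLOGY_EVALUE,
    dissimilarity_e: float = DISSIMILARITY_EVALUE,
) -> LineageCall:
    """Classify one gene from its per-species best e-values.

    ``best_e_values`` maps species label -> best hit e-value (species with no
    hit at all are simply absent). ``fruiting_body_species`` lists the
    fruiting-body-forming basidiomycetes; the gene's own genome must not be
    included there.
    """
    fb = set(fruiting_body_species)
    fb_homologs = sum(
        1 for sp, e in best_e_values.items() if sp in fb and e < homology_e)
    outgroup_hit = any(
        e <= dissimilarity_e for sp, e in best_e_values.items() if sp not in fb)
    any_homolog = any(e < homology_e for e in best_e_values.values())

    if fb_homologs >= 2 and not outgroup_hit:
        classification = BASIDIOMYCETE_UNIQUE
    elif not any_homolog:
        classification = SPECIES_UNIQUE
    else:
        classification = NEITHER
    return LineageCall(gene_id=gene_id, best_e_values=dict(best_e_values),
                       classification=classification)


def classify_lineages(
    gene_ids: Iterable[str],
    reports: Mapping[str, Dict[str, float]],
    fruiting_body_species: Iterable[str],
    **kwargs,
) -> List[LineageCall]:
    """Vector form: ``reports`` maps species -> {query -> best e-value}."""
    calls = []
    for gid in gene_ids:
        evals = {sp: tbl[gid] for sp, tbl in reports.items() if gid in tbl}
        calls.append(classify_lineage(gid, evals, fruiting_body_species, **kwargs))
    return calls


# ---------------------------------------------------------------------------
# table I/O

def read_domain_table(path) -> List[DomainAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["orf_id", "domain_id", "e_value"]:
            raise ValueError(f"{path}: expected orf_id/domain_id/e_value header")
        for line in fh:
            orf, dom, ev = line.rstrip("\n").split("\t")[:3]
            out.append(DomainAssignment(orf, dom, float(ev)))
    return out


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\tk_deg\tn_deg\tk_all\tn_all\tp_value\tenriched\n")
        for r in sorted(results, key=lambda r: r.p_value):
            fh.write(f"{r.domain_id}\t{r.k_deg}\t{r.n_deg}\t{r.k_all}\t"
                     f"{r.n_all}\t{r.p_value:.6g}\t{'yes' if r.enriched else 'no'}\n")


def write_lineage(calls: Sequence[LineageCall], path) -> None:
    species = sorted({sp for c in calls for sp in c.best_e_values})
    with open(path, "w") as fh:
        fh.write("gene_id\tclassification\t" + "\t".join(species) + "\n")
        for c in calls:
            evals = "\t".join(
                f"{c.best_e_values[sp]:.3g}" if sp in c.best_e_values else "."
                for sp in species)
            fh.write(f"{c.gene_id}\t{c.classification}\t{evals}\n")
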