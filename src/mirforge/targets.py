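"""Seed-match target prediction on orthologous 3'-UTR alignments and
hypergeometric enrichment of targets in gene sets.

A target site is the exact reverse complement of the miRNA seed (mature
nucleotides 2-7) found ungapped at homologous alignment columns in every
required species row — conservation across species is the false-positive
filter.  Enrichment of targeted genes in a differentially-expressed set is
the upper tail of the hypergeometric distribution

    p = sum_{i=r}^{min(n,R)} C(R,i) C(N-R, n-i) / C(N,n)

with N the gene universe, R the DE set size, n the targeted-gene count and r
the targeted DE genes; p-values are Benjamini-Hochberg adjusted and gated at
q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

_COMP = str.maketrans("ACGTU", "TGCAA")


def _revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def seed_site(mature: str) -> str:
    """DNA 6-mer a target 3'-UTR must carry: reverse complement of seed nt 2-7."""
    mature = mature.upper().replace("U", "T")
    if len(mature) < 7:
        raise ValueError(f"mature sequence too short for a seed: {mature!r}")
    return _revcomp_dna(mature[1:7])


@dataclass(frozen=True)
class SeedSite:
    gene_id: str
    mirna_id: str
    site: str                 # the 6-mer
    column: int               # alignment column of the site start
    ref_position: int         # ungapped 0-based position in the reference row
    species: frozenset[str]   # required species the site was confirmed in


def find_seed_sites(
    matures: dict[str, str],
    alignments: dict[str, dict[str, str]],
    required_species: tuple[str, ...],
) -> list[SeedSite]:
    """Conserved seed sites: the 6-mer present ungapped at the same alignment
    columns in ALL required species rows.

    ``alignments`` maps gene -> species -> equal-length gapped rows; the
    first required species serves as the reference for ungapped positions.
    """
    if not required_species:
        raise ValueError("required_species must be non-empty")
    sites: list[SeedSite] = []
    site_of = {mid: seed_site(seq) for mid, seq in matures.items()}
    ref_sp = required_species[0]
    for gene in sorted(alignments):
        rows = alignments[gene]
        missing = [sp for sp in required_species if sp not in rows]
        if missing:
            raise ValueError(f"gene {gene}: missing species rows {missing}")
        length = len(rows[ref_sp])
        if any(len(rows[sp]) != length for sp in required_species):
            raise ValueError(f"gene {gene}: unequal alignment row lengths")
        upper = {sp: rows[sp].upper().replace("U", "T") for sp in required_species}
        # ungapped reference position per column
        ref_row = upper[ref_sp]
        ref_pos = np.cumsum([c != "-" for c in ref_row]) - 1
        for mid, site in site_of.items():
            for col in range(length - 5):
                ok = True
                for sp in required_species:
                    window = upper[sp][col:col + 6]
                    if "-" in window or window != site:
                        ok = False
                        break
                if ok:
                    sites.append(SeedSite(
                        gene_id=gene,
                        mirna_id=mid,
                        site=site,
                        column=col,
                        ref_position=int(ref_pos[col]),
                        species=frozenset(required_species),
                    ))
    return sites


def target_map_from_sites(sites: list[SeedSite]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for s in sites:
        out.setdefault(s.mirna_id, set()).add(s.gene_id)
    return out


@dataclass
class EnrichmentInput:
    N: int  # universe of protein-coding genes
    R: int  # differentially expressed genes in the set
    n: int  # genes with predicted target sites
    r: int  # DE genes with predicted target sites

    def __post_init__(self) -> None:
        if not (0 <= self.R <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid contingency {self}")
        if not 0 <= self.r <= min(self.n, self.R):
            raise ValueError(f"r={self.r} exceeds min(n, R) in {self}")


@dataclass
class EnrichmentResult:
    name: str
    inputs: EnrichmentInput
    p: float
    q: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def _log_hyper_term(N: int, R: int, n: int, i: int) -> float:
    # log [ C(R,i) C(N-R, n-i) / C(N,n) ]
    def logC(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return logC(R, i) + logC(N - R, n - i) - logC(N, n)


def hypergeom_pvalue(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability, summed in log space.

    p = sum_{i=r}^{min(n,R)} C(R,i) C(N-R, n-i) / C(N,n).  For r at or below
    the lower support bound the tail is the full distribution and p = 1.
    """
    N, R, n, r = inp.N, inp.R, inp.n, inp.r
    hi = min(n, R)
    lo_support = max(0, n - (N - R))
    if r <= lo_support:
        return 1.0
    terms = np.array([_log_hyper_term(N, R, n, i) for i in range(r, hi + 1)])
    m = terms.max()
    p = float(np.exp(m) * np.exp(terms - m).sum())
    return min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-stable."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_gene_sets(
    target_map: dict[str, set[str]],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    mode: str = "set-level",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of targeted genes within each gene set.

    set-level: one test per gene set against the union of all targeted genes
    (N = universe, n = targeted genes).  per-mirna: one test per
    (miRNA, gene set) with the universe restricted to genes carrying any
    target site (N = genes with any site, n = genes with this miRNA's site).
    BH adjustment is applied within the whole analysis family produced here.
    """
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    for name, genes in gene_sets.items():
        stray = set(genes) - uni
        if stray:
            raise ValueError(f"gene set {name} not contained in universe ({len(stray)} strays)")
    results: list[EnrichmentResult] = []
    if mode == "set-level":
        targeted = set().union(*target_map.values()) if target_map else set()
        targeted &= uni
        for name in sorted(gene_sets):
            genes = set(gene_sets[name])
            inp = EnrichmentInput(N=len(uni), R=len(genes),
                                  n=len(targeted), r=len(genes & targeted))
            results.append(EnrichmentResult(name=name, inputs=inp, p=hypergeom_pvalue(inp)))
    elif mode == "per-mirna":
        any_site = set().union(*target_map.values()) if target_map else set()
        any_site &= uni
        for mid in sorted(target_map):
            hits = target_map[mid] & any_site
            for name in sorted(gene_sets):
                genes = set(gene_sets[name]) & any_site
                inp = EnrichmentInput(N=len(any_site), R=len(genes),
                                      n=len(hits), r=len(genes & hits))
                results.append(EnrichmentResult(name=f"{mid}|{name}", inputs=inp,
                                                p=hypergeom_pvalue(inp)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    qs = bh_adjust([r.p for r in results])
    for res, q in zip(results, qs):
        res.q = float(q)
    return results
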