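"""Length-weighted resampling test for PR-domain mutation enrichment.

Null model: each of the gene's deleterious missense mutations lands
independently at a uniformly random residue of the canonical protein, so
the chance of hitting any region is proportional to that region's length
in amino acids ("weighted on the size of the annotated domains").  Each
iteration redraws all mutation positions; the one-sided p-value uses the
add-one estimator

    p = (1 + #{null draws with PR count >= observed}) / (1 + iterations)

which can never return exactly zero from finite resampling.  On a protein
whose only annotated region is the PR domain of relative length f, the
null PR count is Binomial(n, f), which the tests use as the exact oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .consequence import Call, classify_deleterious
from .exceptions import ConfigurationError, DomainInputError
from .maf import DomainKind, MutationRecord, ProteinModel, VariantClass

logger = logging.getLogger(__name__)

NO_DOMAIN = "none"


@dataclass(frozen=True)
class EnrichmentResult:
    gene_symbol: str
    target_kind: DomainKind
    n_mutations: int
    observed_in_domain: int
    iterations: int
    null_counts: np.ndarray
    p_value: float
    expected_mean: float
    seed: int | None

    def __post_init__(self) -> None:
        assert self.observed_in_domain <= self.n_mutations
        assert len(self.null_counts) == self.iterations


def map_to_domains(
    records: Sequence[MutationRecord],
    protein_model: ProteinModel,
) -> dict[str, int]:
    """Assign each mutation with a protein position to exactly one bucket.

    Buckets: ``PR``, ``ZnF``, ``OTHER`` (any other annotated domain) and
    ``none`` (outside all domains).  Bucket sums equal the number of
    usable records; positions outside [1, length] are excluded with a
    warning.
    """
    buckets = {DomainKind.PR.value: 0, DomainKind.ZNF.value: 0,
               DomainKind.OTHER.value: 0, NO_DOMAIN: 0}
    for r in records:
        pos = r.protein_position
        if pos is None:
            continue
        if not (1 <= pos <= protein_model.length_aa):
            logger.warning(
                "%s: position %d outside [1, %d]; excluded from domain mapping",
                protein_model.gene_symbol, pos, protein_model.length_aa,
            )
            continue
        dom = protein_model.domain_at(pos)
        buckets[dom.kind.value if dom else NO_DOMAIN] += 1
    return buckets


def deleterious_missense(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """The record subset the enrichment test operates on."""
    return [
        r
        for r in records
        if r.variant_class is VariantClass.MISSENSE
        and r.protein_position is not None
        and classify_deleterious(r).call is Call.DELETERIOUS
    ]


def pr_enrichment_test(
    records: Sequence[MutationRecord],
    protein_model: ProteinModel,
    iterations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Is the PR domain hit more often than size-weighted chance predicts?

    ``records`` must be restricted to one gene's deleterious missense
    mutations with in-bounds protein positions (see
    :func:`deleterious_missense`); each record is one independent draw.
    """
    pr = protein_model.pr_domains()
    if not pr:
        raise ConfigurationError(
            f"{protein_model.gene_symbol}: no PR domain annotated"
        )
    positions = np.array(
        [r.protein_position for r in records if r.protein_position is not None],
        dtype=np.int64,
    )
    positions = positions[(positions >= 1) & (positions <= protein_model.length_aa)]
    n = len(positions)
    if n == 0:
        raise DomainInputError(
            f"{protein_model.gene_symbol}: no usable mutations for enrichment test"
        )

    in_pr = np.zeros(protein_model.length_aa + 1, dtype=bool)
    for d in pr:
        in_pr[d.start_aa : d.end_aa + 1] = True
    observed = int(in_pr[positions].sum())

    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.integers(1, protein_model.length_aa + 1, size=(iterations, n))
    null_counts = in_pr[draws].sum(axis=1)
    p = (1 + int((null_counts >= observed).sum())) / (1 + iterations)
    return EnrichmentResult(
        gene_symbol=protein_model.gene_symbol,
        target_kind=DomainKind.PR,
        n_mutations=n,
        observed_in_domain=observed,
        iterations=iterations,
        null_counts=null_counts,
        p_value=p,
        expected_mean=float(null_counts.mean()),
        seed=seed,
    )


def enrichment_table(
    records_by_gene: Mapping[str, Sequence[MutationRecord]],
    models: Mapping[str, ProteinModel],
    iterations: int = 1000,
    seed: int | None = None,
):
    """Run the PR enrichment test per gene; returns a tidy DataFrame.

    Genes without a PR domain or without usable mutations are skipped.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    rows = []
    genes = sorted(records_by_gene)
    streams = ss.spawn(len(genes))
    for gene, child in zip(genes, streams):
        model = models.get(gene)
        if model is None or not model.pr_domains():
            continue
        subset = deleterious_missense(records_by_gene[gene])
        if not subset:
            continue
        res = pr_enrichment_test(
            subset, model, iterations=iterations, rng=np.random.default_rng(child)
        )
        rows.append({
            "gene_symbol": gene,
            "n_mutations": res.n_mutations,
            "observed_in_pr": res.observed_in_domain,
            "expected_mean": res.expected_mean,
            "p_value": res.p_value,
            "iterations": iterations,
            "seed": seed,
        })
    return pd.DataFrame(
        rows,
        columns=["gene_symbol", "n_mutations", "observed_in_pr",
                 "expected_mean", "p_value", "iterations", "seed"],
    )
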