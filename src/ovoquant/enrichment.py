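"""Binomial over-representation analysis of protein lists.

For each annotation term, the number of list proteins carrying the term
is compared with the expectation under the term's frequency in a
reference set, using an upper-tail binomial test (the convention of
classic gene-list over-representation tools), with Bonferroni control
over the number of terms actually tested.  Fold enrichment is
observed / expected.  A hypergeometric variant is available for users
who prefer sampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core_data import ValidationError

__all__ = ["EnrichmentRecord", "overrepresentation_test", "underrepresentation_p"]


@dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    k_list: int          # list proteins with the term
    n_list: int          # list size
    K_ref: int           # reference proteins with the term
    N_ref: int           # reference size
    expected: float      # n_list * K_ref / N_ref
    fold_enrichment: float
    p_raw: float
    p_adj: float         # Bonferroni: min(1, p_raw * number of tested terms)


def _binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))


def overrepresentation_test(list_ids: set, reference_ids: set,
                            annotations: pd.DataFrame,
                            method: str = "binomial") -> list[EnrichmentRecord]:
    """Term over-representation of ``list_ids`` against ``reference_ids``.

    ``annotations`` is a long frame with columns protein_id, term_id,
    term_name.  Terms with no reference member are skipped.  Records
    are returned sorted by adjusted p.
    """
    if not list_ids or not reference_ids:
        raise ValidationError("list and reference must be nonempty")
    extra = set(list_ids) - set(reference_ids)
    if extra:
        raise ValidationError(
            f"list protein {sorted(extra)[0]!r} missing from the reference set")
    ann = annotations[annotations["protein_id"].isin(reference_ids)]
    n_list, N_ref = len(list_ids), len(reference_ids)

    terms = []
    for (term_id, term_name), block in ann.groupby(["term_id", "term_name"], sort=False):
        members = set(block["protein_id"])
        K_ref = len(members)
        if K_ref == 0:
            continue
        k_list = len(members & list_ids)
        expected = n_list * K_ref / N_ref
        if method == "binomial":
            p_raw = _binom_upper_tail(k_list, n_list, K_ref / N_ref)
        elif method == "hypergeometric":
            p_raw = float(stats.hypergeom.sf(k_list - 1, N_ref, K_ref, n_list))
        else:
            raise ValidationError(f"unknown method {method!r}")
        terms.append(EnrichmentRecord(
            term_id=str(term_id), term_name=str(term_name),
            k_list=k_list, n_list=n_list, K_ref=K_ref, N_ref=N_ref,
            expected=expected,
            fold_enrichment=k_list / expected if expected > 0 else float("nan"),
            p_raw=p_raw, p_adj=1.0))
    m = len(terms)
    for rec in terms:
        rec.p_adj = min(1.0, rec.p_raw * m)
    terms.sort(key=lambda r: (r.p_adj, r.p_raw))
    return terms


def underrepresentation_p(k_list: int, n_list: int, K_ref: int, N_ref: int) -> float:
    """Lower-tail binomial probability P(X <= k_list)."""
    if n_list <= 0 or N_ref <= 0:
        raise ValidationError("list and reference sizes must be positive")
    return float(stats.binom.cdf(k_list, n_list, K_ref / N_ref))
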