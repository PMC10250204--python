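"""Per-exon metrics (Fupfi, PSI, PIR), output table, categories and consistency stats."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from insplico.annotation import ExonEntity
from insplico.classify import AISOCounts

NA = float("nan")

CATEGORY_NA = "NA"
CATEGORIES = ("upfi", "dofi", "intermediate")

OUTPUT_COUNT_COLUMNS = (
    "upfi", "dofi", "bus", "bos", "skip", "inup", "indo",
    "ei_up", "ei_do", "nb_up", "nb_do", "discarded",
)
OUTPUT_METRIC_COLUMNS = ("fupfi", "psi", "pir_up", "pir_do")


@dataclass
class ExonMetrics:
    """Counts plus derived fractions for one exon row; NaN encodes NA."""

    counts: AISOCounts
    fupfi: float
    psi: float
    pir_up: float
    pir_do: float


def fupfi(counts: AISOCounts) -> float:
    """upfi / (upfi + dofi); NA when the denominator is zero."""
    denom = counts.upfi + counts.dofi
    if denom == 0:
        return NA
    return counts.upfi / denom


def psi(counts: AISOCounts) -> float:
    """Proportion spliced-in from inclusion/skipping junction counts."""
    inc = (counts.inup + counts.indo) / 2
    denom = inc + counts.skip
    if denom == 0:
        return NA
    return inc / denom


def pir(side: str, counts: AISOCounts) -> float:
    """Proportion of intron retention of the chosen flanking intron.

    Averages the two unspliced boundary-span counts of the intron and
    relates them to the spliced junction count across it.
    """
    if side == "up":
        unspliced = (counts.nb_up + counts.ei_up) / 2
        spliced = counts.inup
    elif side == "do":
        unspliced = (counts.ei_do + counts.nb_do) / 2
        spliced = counts.indo
    else:
        raise ValueError(f"side must be 'up' or 'do', got {side!r}")
    denom = unspliced + spliced
    if denom == 0:
        return NA
    return unspliced / denom


def compute_metrics(counts: AISOCounts) -> ExonMetrics:
    return ExonMetrics(
        counts=counts,
        fupfi=fupfi(counts),
        psi=psi(counts),
        pir_up=pir("up", counts),
        pir_do=pir("do", counts),
    )


def metrics_frame(
    rows: Sequence[ExonMetrics], entities: Optional[Sequence[ExonEntity]] = None
) -> pd.DataFrame:
    """Assemble the output table, one row per input exon, input order preserved."""
    if entities is not None and len(entities) != len(rows):
        raise ValueError(f"{len(entities)} entities but {len(rows)} metric rows")
    data: dict[str, list] = {}
    if entities is not None:
        data["chrom"] = [e.chrom for e in entities]
        data["strand"] = [e.strand for e in entities]
        data["exon_start"] = [e.extent[0] + 1 for e in entities]
        data["exon_end"] = [e.extent[1] for e in entities]
        data["gene_id"] = [e.gene_id for e in entities]
        data["exon_type"] = [e.exon_type for e in entities]
    for col in OUTPUT_COUNT_COLUMNS:
        data[col] = [getattr(r.counts, col) for r in rows]
    for col in OUTPUT_METRIC_COLUMNS:
        data[col] = [getattr(r, col) for r in rows]
    return pd.DataFrame(data)


def write_output(
    rows: Sequence[ExonMetrics],
    path: str,
    entities: Optional[Sequence[ExonEntity]] = None,
) -> None:
    """Write the tab-separated result table; undefined values as literal ``NA``."""
    metrics_frame(rows, entities).to_csv(path, sep="\t", index=False, na_rep="NA",
                                         float_format="%.6g")


def read_output(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def categorize(
    fupfi_values: Sequence[float],
    totals: Sequence[int],
    hi: float = 0.8,
    lo: float = 0.2,
    min_reads: int = 10,
) -> list[str]:
    """AISO category per exon: upfi (Fupfi >= hi), dofi (<= lo), intermediate,
    or NA when upfi+dofi < min_reads or Fupfi undefined."""
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    out = []
    for f, n in zip(fupfi_values, totals, strict=True):
        if n < min_reads or f is None or math.isnan(f):
            out.append(CATEGORY_NA)
        elif f >= hi:
            out.append("upfi")
        elif f <= lo:
            out.append("dofi")
        else:
            out.append("intermediate")
    return out


def consistency_test(
    cat_query: Sequence[str],
    cat_target: Sequence[str],
    fupfi_query: Optional[Sequence[float]] = None,
    fupfi_target: Optional[Sequence[float]] = None,
) -> dict:
    """Category overlap between conditions with a one-sided binomial test.

    For each query category c: of the n shared exons that are c in the
    query, k are also c in the target; the background p0 is the fraction of
    c among all shared exons in the target; the p-value is P(X >= k) with
    X ~ Binomial(n, p0). Also reports Pearson/Spearman correlations of the
    Fupfi values when given.
    """
    if len(cat_query) != len(cat_target):
        raise ValueError("category vectors differ in length")
    defined = [
        i
        for i in range(len(cat_query))
        if cat_query[i] != CATEGORY_NA and cat_target[i] != CATEGORY_NA
    ]
    result: dict = {"n_shared": len(defined), "categories": {}}
    n_shared = len(defined)
    for cat in CATEGORIES:
        idx = [i for i in defined if cat_query[i] == cat]
        n = len(idx)
        k = sum(1 for i in idx if cat_target[i] == cat)
        p0 = (
            sum(1 for i in defined if cat_target[i] == cat) / n_shared
            if n_shared
            else NA
        )
        if n == 0:
            result["categories"][cat] = {
                "n": 0, "k": 0, "overlap": NA, "background": p0, "p_value": NA,
            }
            continue
        p_value = float(stats.binom.sf(k - 1, n, p0))
        result["categories"][cat] = {
            "n": n,
            "k": k,
            "overlap": k / n,
            "background": p0,
            "p_value": p_value,
        }
    if fupfi_query is not None and fupfi_target is not None:
        pairs = [
            (fupfi_query[i], fupfi_target[i])
            for i in defined
            if not math.isnan(fupfi_query[i]) and not math.isnan(fupfi_target[i])
        ]
        if len(pairs) >= 2:
            x, y = np.array(pairs).T
            if np.std(x) == 0 or np.std(y) == 0:
                # degenerate: constant vector; correlation undefined unless identical
                result["pearson"] = 1.0 if np.allclose(x, y) else NA
                result["spearman"] = 1.0 if np.allclose(x, y) else NA
            else:
                result["pearson"] = float(stats.pearsonr(x, y)[0])
                result["spearman"] = float(stats.spearmanr(x, y)[0])
        else:
            result["pearson"] = NA
            result["spearman"] = NA
    return result
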