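"""Module–lifestyle association tests for bacteriophages.

Lifestyle annotations (temperate vs virulent) typically cover only a small
fraction of genomes, so modules with labels for fewer than 10% of their
members are not tested.  For tested modules, a one-sided exact binomial
test asks whether the majority lifestyle among labeled members is more
frequent than expected under the background proportion (module composition
random with respect to lifestyle).  No multiple-testing correction is
applied; raw p values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import binomtest

from .genomes import GenomeSet


@dataclass
class LifestyleTestResult:
    module: str
    tested: bool
    direction: str | None = None  # majority lifestyle among labeled members
    k: int = 0  # count of the majority lifestyle
    n: int = 0  # labeled members
    p0: float | None = None  # background fraction of that lifestyle
    p_value: float | None = None
    coverage: float = 0.0


def binomial_enrichment_p(k: int, n: int, p0: float) -> float:
    """One-sided exact upper-tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    return float(binomtest(k, n, p0, alternative="greater").pvalue)


def module_lifestyle_test(
    module: str,
    members: set[str],
    labels: dict[str, str],
    background: tuple[int, int],
    min_coverage: float = 0.10,
) -> LifestyleTestResult:
    """Test one module for lifestyle enrichment.

    Parameters
    ----------
    members
        Genome ids of the module.
    labels
        genome_id → lifestyle; genomes absent or ``unknown`` are unlabeled.
    background
        (n_temperate, n_virulent) in the reference collection; both must be
        positive so the null proportion is well defined.
    """
    n_temp_bg, n_vir_bg = background
    if n_temp_bg <= 0 or n_vir_bg <= 0:
        raise ValueError("background counts must be positive")
    labeled = {
        g: labels[g]
        for g in members
        if labels.get(g, "unknown") in ("temperate", "virulent")
    }
    coverage = len(labeled) / len(members) if members else 0.0
    if not members or coverage < min_coverage or not labeled:
        return LifestyleTestResult(module, tested=False, coverage=coverage)
    n_temp = sum(1 for v in labeled.values() if v == "temperate")
    n_vir = len(labeled) - n_temp
    # majority direction; ties resolve to temperate for determinism
    if n_temp >= n_vir:
        direction, k = "temperate", n_temp
        p0 = n_temp_bg / (n_temp_bg + n_vir_bg)
    else:
        direction, k = "virulent", n_vir
        p0 = n_vir_bg / (n_temp_bg + n_vir_bg)
    p = binomial_enrichment_p(k, len(labeled), p0)
    return LifestyleTestResult(
        module, True, direction, k, len(labeled), p0, p, coverage
    )


def lifestyle_association_table(
    modules: dict[str, set[str]],
    genomes: GenomeSet,
    background: tuple[int, int] | None = None,
    min_coverage: float = 0.10,
) -> pd.DataFrame:
    """Lifestyle tests for every module; background defaults to the labeled totals."""
    labels = genomes.lifestyle
    if background is None:
        n_temp = sum(1 for v in labels.values() if v == "temperate")
        n_vir = sum(1 for v in labels.values() if v == "virulent")
        background = (n_temp, n_vir)
    rows = []
    for mod, members in modules.items():
        if background[0] <= 0 or background[1] <= 0:
            res = LifestyleTestResult(str(mod), tested=False)
        else:
            res = module_lifestyle_test(
                str(mod), members, labels, background, min_coverage
            )
        rows.append(
            (
                res.module,
                len(members),
                res.coverage,
                res.tested,
                res.direction,
                res.k,
                res.n,
                res.p0,
                res.p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "module",
            "n_members",
            "coverage",
            "tested",
            "direction",
            "k",
            "n_labeled",
            "p0",
            "p_value",
        ],
    )
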