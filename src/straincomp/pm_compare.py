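"""Between-strain activity comparison: the ΔA specificity statistic,
scatter-band table and substrate-to-enzyme association.

For every substrate assayed in both strains, ΔA = A(strain2) -
A(strain1).  Over all substrates the mean μ_A and sample standard
deviation σ_A of ΔA are computed; substrates in the tails are called
strain-specific:

* zero-centered rule (default): ΔA < -σ_A ⇒ strain1-specific,
  ΔA > +σ_A ⇒ strain2-specific, otherwise shared;
* mean-centered rule: the same with cutpoints at μ_A ± σ_A.

The two rules coincide when μ_A = 0 and genuinely disagree otherwise;
both are exposed because published scatter plots draw the band lines at
the mean while the stated call rule reads as zero-centered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "DeltaAResult",
    "EcAssociation",
    "delta_a_classify",
    "scatter_table",
    "ec_association",
    "load_ec_map",
    "packaged_ec_map",
]

_EC_PATTERN = re.compile(r"^\d+(\.(\d+|-)){1,3}$")


@dataclass
class DeltaAResult:
    substrate: str
    a_strain1: float
    a_strain2: float
    delta_a: float
    mu_a: float
    sigma_a: float
    call: str  # 'strain1-specific' | 'strain2-specific' | 'shared'


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


def delta_a_classify(
    activities_strain1: Dict[str, float],
    activities_strain2: Dict[str, float],
    centering: str = "zero",
) -> List[DeltaAResult]:
    """Classify substrates as strain-specific from the ΔA distribution.

    Both inputs map substrate name to activity and must cover the same
    substrates.  σ_A uses the n-1 denominator; when σ_A = 0 every
    substrate is shared.
    """
    if centering not in ("zero", "mean"):
        raise ValueError(f"unknown centering {centering!r}")
    k1, k2 = list(activities_strain1), list(activities_strain2)
    if [_normalize_name(s) for s in k1] != [_normalize_name(s) for s in k2]:
        raise ValueError("substrate lists of the two strains do not match")
    if len(k1) < 2:
        raise ValueError("need at least 2 substrates to estimate sigma_A")

    a1 = np.array([activities_strain1[s] for s in k1], dtype=float)
    a2 = np.array([activities_strain2[s] for s in k2], dtype=float)
    delta = a2 - a1
    mu = float(np.mean(delta))
    sigma = float(np.std(delta, ddof=1))
    center = mu if centering == "mean" else 0.0

    results = []
    for sub, x1, x2, d in zip(k1, a1, a2, delta):
        if sigma == 0:
            call = "shared"
        elif d < center - sigma:
            call = "strain1-specific"
        elif d > center + sigma:
            call = "strain2-specific"
        else:
            call = "shared"
        results.append(DeltaAResult(sub, float(x1), float(x2), float(d), mu, sigma, call))
    return results


def scatter_table(results: Sequence[DeltaAResult]) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-substrate activity pairs plus the diagonal band offsets.

    The offsets are such that lines ``y = x + offset`` drawn over the
    (strain1, strain2) scatter reproduce the μ_A, μ_A ± σ_A and
    μ_A ± 2σ_A bands.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 substrates")
    mu, sigma = results[0].mu_a, results[0].sigma_a
    df = pd.DataFrame(
        {
            "substrate": [r.substrate for r in results],
            "a_strain1": [r.a_strain1 for r in results],
            "a_strain2": [r.a_strain2 for r in results],
            "delta_a": [r.delta_a for r in results],
            "call": [r.call for r in results],
        }
    )
    offsets = {
        "mu": mu,
        "mu_plus_sigma": mu + sigma,
        "mu_minus_sigma": mu - sigma,
        "mu_plus_2sigma": mu + 2 * sigma,
        "mu_minus_2sigma": mu - 2 * sigma,
    }
    return df, offsets


@dataclass
class EcAssociation:
    substrate: str
    ec_codes: Union[List[str], str]  # list of EC codes or the literal "unknown"


def load_ec_map(path) -> Dict[str, List[str]]:
    """Read a substrate→EC mapping TSV: ``substrate<TAB>EC;EC;...``.

    EC tokens must match the dotted pattern with optional trailing
    dashes (e.g. ``1.14.13.22``, ``1.14.13.-``).
    """
    mapping: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            ecs = [e.strip() for e in re.split(r"[;,]", parts[1]) if e.strip()]
            for ec in ecs:
                if not _EC_PATTERN.match(ec):
                    raise ValueError(f"{path}:{lineno}: malformed EC code {ec!r}")
            mapping[_normalize_name(parts[0])] = ecs
    return mapping


def packaged_ec_map() -> Dict[str, List[str]]:
    """The packaged substrate→EC map for the xenobiotic PM panel."""
    ref = resources.files("straincomp.data") / "xenobiotic_ec_map.tsv"
    with resources.as_file(ref) as path:
        return load_ec_map(path)


def ec_association(
    substrates: Sequence[str], mapping: Optional[Dict[str, List[str]]] = None
) -> List[EcAssociation]:
    """Associate substrates with enzyme EC codes; unmapped ones are "unknown".

    Substrate names are matched case-insensitively after whitespace
    normalization.  ``mapping`` defaults to the packaged xenobiotic map.
    """
    if mapping is None:
        mapping = packaged_ec_map()
    else:
        mapping = {_normalize_name(k): v for k, v in mapping.items()}
    out = []
    for sub in substrates:
        codes = mapping.get(_normalize_name(sub))
        out.append(EcAssociation(sub, list(codes) if codes else "unknown"))
    return out
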