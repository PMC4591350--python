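"""Synthetic genomes, CDS annotations and phenotype-microarray plates
with known ground truth.

Every downstream stage of the pipeline is testable without any
downloaded data:

* :func:`simulate_genome_set` builds multi-replicon genomes out of
  planted shared blocks (verbatim copies across member genomes,
  optionally reordered/inverted), planted unique blocks, and i.i.d.
  uniform random DNA background, recording exact coordinates;
* :func:`simulate_cds_annotation` scatters non-overlapping CDSs with a
  controlled hypothetical-protein fraction and functional categories;
* :func:`simulate_pm_curve` / :func:`simulate_pm_plate` produce sigmoid
  kinetic curves (logistic, Gompertz or Richards) with additive Gaussian
  noise clipped at zero, and a plate-level truth naming which substrates
  are strain-specific.

All generators are deterministic given their seed: the same call twice
produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .annotation import HYPOTHETICAL, CdsRecord
from .genome import Genome
from .models import MODELS
from .pm_kinetics import DEFAULT_GRID, KineticCurve
from .regions import RegionSet

__all__ = [
    "GenomeTruth",
    "PlateTruth",
    "simulate_genome_set",
    "simulate_cds_annotation",
    "simulate_pm_curve",
    "simulate_pm_plate",
]

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _DNA[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass
class GenomeTruth:
    """Planted ground truth for one simulated genome."""

    genome_id: str
    # (replicon, start, end, partner genome ids)
    planted_shared_blocks: List[Tuple[str, int, int, Tuple[str, ...]]]
    planted_unique_regions: RegionSet
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "planted_shared_blocks": [
                {"replicon": r, "start": s, "end": e, "partners": list(p)}
                for r, s, e, p in self.planted_shared_blocks
            ],
            "planted_unique_regions": {
                rep: [[s, e] for s, e in ivs]
                for rep, ivs in self.planted_unique_regions.regions.items()
            },
            "seed": self.seed,
        }


@dataclass
class PlateTruth:
    """Ground truth for one simulated two-strain PM plate."""

    substrate_ids: List[str]
    # (substrate, strain) -> (model name, params dict)
    true_model_params: Dict[Tuple[str, str], Tuple[str, Dict[str, float]]]
    noise_sd: float
    specific_for: Dict[str, str]  # substrate -> strain id or 'none'
    seed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "substrate_ids": self.substrate_ids,
            "true_model_params": {
                f"{sub}|{strain}": {"model": m, "params": p}
                for (sub, strain), (m, p) in self.true_model_params.items()
            },
            "noise_sd": self.noise_sd,
            "specific_for": self.specific_for,
            "seed": self.seed,
        }


def simulate_genome_set(
    n_genomes: int,
    replicon_plan: Sequence[Sequence[int]],
    shared_block_spec: Sequence[Tuple[int, Sequence[Union[int, str]]]] = (),
    unique_block_spec: Sequence[Tuple[int, Union[int, str]]] = (),
    rearrange: bool = False,
    seed: int = 0,
) -> Tuple[List[Genome], Dict[str, GenomeTruth]]:
    """Simulate genomes with planted shared and unique blocks.

    ``replicon_plan[i]`` lists replicon lengths for genome i.  Shared
    blocks are drawn once and copied verbatim into every member genome
    (members given as 0-based indices or genome ids); with ``rearrange``
    each genome receives its blocks in an independently shuffled order
    and shared blocks may be strand-inverted.  Blocks are packed
    left-to-right, first-fit across a genome's replicons; space not
    taken by blocks is filled with independent random DNA.

    Raises a capacity ``ValueError`` when the planned blocks do not fit.
    """
    if len(replicon_plan) != n_genomes:
        raise ValueError("replicon_plan must list lengths for every genome")
    for plan in replicon_plan:
        if any(length <= 0 for length in plan):
            raise ValueError("replicon lengths must be positive")
    for length, _ in list(shared_block_spec) + list(unique_block_spec):
        if length <= 0:
            raise ValueError("block lengths must be positive")

    genome_ids = [f"g{i + 1}" for i in range(n_genomes)]

    def _gid(ref: Union[int, str]) -> str:
        return genome_ids[ref] if isinstance(ref, int) else ref

    rng = np.random.default_rng(seed)
    shared_seqs = [_random_dna(rng, length) for length, _ in shared_block_spec]
    unique_seqs = [_random_dna(rng, length) for length, _ in unique_block_spec]

    genomes: List[Genome] = []
    truths: Dict[str, GenomeTruth] = {}
    for i, gid in enumerate(genome_ids):
        members_of = [
            (b, tuple(_gid(m) for m in members))
            for b, (_, members) in enumerate(shared_block_spec)
            if gid in {_gid(m) for m in members}
        ]
        blocks: List[Tuple[str, str, Tuple[str, ...]]] = [
            ("shared", shared_seqs[b], tuple(p for p in partners if p != gid))
            for b, partners in members_of
        ]
        blocks += [
            ("unique", unique_seqs[u], ())
            for u, (_, owner) in enumerate(unique_block_spec)
            if _gid(owner) == gid
        ]
        if rearrange:
            order = rng.permutation(len(blocks))
            invert = rng.random(len(blocks)) < 0.5
            blocks = [
                (
                    kind,
                    seq.translate(_COMPLEMENT)[::-1] if kind == "shared" and invert[j] else seq,
                    partners,
                )
                for j, (kind, seq, partners) in ((j, blocks[o]) for j, o in enumerate(order))
            ]

        rep_lengths = list(replicon_plan[i])
        rep_ids = [f"{gid}_r{j + 1}" for j in range(len(rep_lengths))]
        parts: Dict[str, List[str]] = {r: [] for r in rep_ids}
        shared_truth: List[Tuple[str, int, int, Tuple[str, ...]]] = []
        unique_truth: Dict[str, List[Tuple[int, int]]] = {}
        r, cursor = 0, 0
        for kind, seq, partners in blocks:
            while r < len(rep_lengths) and cursor + len(seq) > rep_lengths[r]:
                parts[rep_ids[r]].append(_random_dna(rng, rep_lengths[r] - cursor))
                r, cursor = r + 1, 0
            if r == len(rep_lengths):
                raise ValueError(
                    f"block plan exceeds replicon capacity of genome {gid!r}"
                )
            parts[rep_ids[r]].append(seq)
            if kind == "shared":
                shared_truth.append((rep_ids[r], cursor, cursor + len(seq), partners))
            else:
                unique_truth.setdefault(rep_ids[r], []).append((cursor, cursor + len(seq)))
            cursor += len(seq)
        # fill the remainder of the genome with random background
        while r < len(rep_lengths):
            parts[rep_ids[r]].append(_random_dna(rng, rep_lengths[r] - cursor))
            r, cursor = r + 1, 0

        replicons = {rid: "".join(parts[rid]) for rid in rep_ids}
        genomes.append(Genome(gid, replicons))
        truths[gid] = GenomeTruth(
            gid,
            shared_truth,
            RegionSet.from_intervals(gid, unique_truth),
            seed,
        )
    return genomes, truths


_PRODUCT_POOL = [
    "alkane 1-monooxygenase",
    "cyclohexanone monooxygenase",
    "catechol 1,2-dioxygenase",
    "acyl-CoA dehydrogenase",
    "ABC transporter ATP-binding protein",
    "TetR family transcriptional regulator",
    "rubredoxin reductase",
    "long-chain-fatty-acid--CoA ligase",
    "enoyl-CoA hydratase",
    "aldehyde dehydrogenase",
]

_EC_POOL = [
    "1.14.13.22", "1.3.99.14", "6.2.1.3", "1.13.11.4",
    "1.14.12.12", "1.2.1.3", "4.2.1.17", "1.3.8.7",
]

_DEFAULT_CATEGORIES = {
    "Carbohydrates": 4.0,
    "Amino Acids and Derivatives": 3.0,
    "Fatty Acids, Lipids and Isoprenoids": 2.0,
    "Metabolism of Aromatic Compounds": 1.0,
    "Stress Response": 1.0,
}


def simulate_cds_annotation(
    genome: Genome,
    mean_cds_len: int = 900,
    density: float = 0.8,
    hypothetical_fraction: float = 0.35,
    category_weights: Optional[Dict[str, float]] = None,
    ec_fraction: float = 0.2,
    seed: int = 0,
) -> List[CdsRecord]:
    """Scatter non-overlapping CDSs over a genome, both strands.

    ``density`` is CDSs per kb; products are "hypothetical protein" with
    the stated fraction, otherwise drawn from a small vocabulary of
    plausible bacterial products; each CDS carries one category sampled
    from ``category_weights``; a fraction of non-hypothetical CDSs get
    an EC number.  CDSs are laid out left to right with random
    intergenic gaps; a plan whose CDSs cannot fit on a replicon raises a
    placement ``ValueError``.
    """
    if not (0 <= hypothetical_fraction <= 1):
        raise ValueError("hypothetical_fraction must be in [0, 1]")
    if density <= 0:
        raise ValueError("density must be > 0")
    weights = category_weights or _DEFAULT_CATEGORIES
    cats = list(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("category weights must have positive sum")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    records: List[CdsRecord] = []
    counter = 0
    for rep, seq in genome.replicons.items():
        L = len(seq)
        n_cds = int(round(density * L / 1000.0))
        if n_cds == 0:
            continue
        lengths = np.clip(
            rng.normal(mean_cds_len, 0.3 * mean_cds_len, size=n_cds), 90, max(L, 90)
        ).astype(int)
        lengths -= lengths % 3
        total = int(lengths.sum())
        if total > L:
            raise ValueError(
                f"could not place {n_cds} CDSs totalling {total} bp on {rep} "
                f"({L} bp): density {density}/kb too high"
            )
        # CDSs laid out left to right with random intergenic gaps
        gaps = rng.multinomial(L - total, np.full(n_cds + 1, 1.0 / (n_cds + 1)))
        cursor = 0
        placed: List[Tuple[int, int]] = []
        for gap, length in zip(gaps[:-1], lengths):
            cursor += int(gap)
            placed.append((cursor, cursor + int(length)))
            cursor += int(length)
        for start, end in placed:
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < hypothetical_fraction:
                product, ecs = HYPOTHETICAL, []
            else:
                product = _PRODUCT_POOL[int(rng.integers(0, len(_PRODUCT_POOL)))]
                ecs = (
                    [str(rng.choice(_EC_POOL))] if rng.random() < ec_fraction else []
                )
            category = str(rng.choice(cats, p=probs))
            records.append(
                CdsRecord(
                    cds_id=f"{genome.genome_id}_cds{counter:05d}",
                    replicon=rep,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    category=category,
                    ec_numbers=ecs,
                )
            )
    records.sort(key=lambda c: (c.replicon, c.start))
    return records


def _unpack_params(model: str, params) -> Dict[str, float]:
    if isinstance(params, dict):
        out = dict(params)
    else:
        names = ["A", "mu", "lambda_", "y0", "nu"]
        out = dict(zip(names, params))
    out.setdefault("y0", 0.0)
    if model == "richards":
        out.setdefault("nu", 1.0)
    else:
        out.pop("nu", None)
    return {k: float(v) for k, v in out.items()}


def simulate_pm_curve(
    model: str,
    params,
    t_grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    strain_id: str = "strain",
    plate_id: str = "plate",
    well_id: str = "w01",
    substrate: Optional[str] = None,
    replicate: int = 1,
) -> KineticCurve:
    """One noisy sigmoid kinetic curve on the 15-min/72-h grid.

    ``params`` is (A, mu, lambda, y0[, nu]) or an equivalent dict.
    Gaussian noise of standard deviation ``noise_sd`` is added and the
    signal clipped at zero (the reader reports non-negative units).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    p = _unpack_params(model, params)
    if p["A"] < 0:
        raise ValueError("amplitude A must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = DEFAULT_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    y = MODELS[model](t, **p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    y = np.clip(y, 0.0, None)
    return KineticCurve(
        strain_id, plate_id, well_id, substrate or well_id, replicate, t, y
    )


def _noiseless_auc(model: str, p: Dict[str, float], t: np.ndarray) -> float:
    y = MODELS[model](t, **p)
    return float(np.trapezoid(np.clip(y - p["y0"], 0, None), t))


def simulate_pm_plate(
    strain_ids: Tuple[str, str],
    effect_spec: Dict[str, Dict[str, object]],
    n_substrates: Optional[int] = None,
    n_replicates: int = 2,
    noise_sd: float = 5.0,
    model: str = "gompertz",
    plate_id: str = "PMS1",
    t_grid: Optional[np.ndarray] = None,
    seed: int = 0,
    specificity_rel_diff: float = 0.5,
) -> Tuple[List[KineticCurve], PlateTruth]:
    """Simulate a two-strain plate: strain x substrate x replicate curves.

    ``effect_spec`` maps each substrate to per-strain model parameters
    (missing strain entries raise a specification error).  The truth
    labels a substrate strain-specific when that strain's noiseless AUC
    is strictly larger and the relative difference (against the larger
    AUC) exceeds ``specificity_rel_diff``; otherwise 'none'.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    substrates = list(effect_spec)
    if n_substrates is not None and n_substrates != len(substrates):
        raise ValueError(
            f"effect_spec defines {len(substrates)} substrates, expected {n_substrates}"
        )
    t = DEFAULT_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)

    curves: List[KineticCurve] = []
    true_params: Dict[Tuple[str, str], Tuple[str, Dict[str, float]]] = {}
    specific_for: Dict[str, str] = {}
    for w, sub in enumerate(substrates, 1):
        per_strain = effect_spec[sub]
        aucs = {}
        for strain in strain_ids:
            if strain not in per_strain:
                raise ValueError(f"substrate {sub!r}: no parameters for strain {strain!r}")
            p = _unpack_params(model, per_strain[strain])
            true_params[(sub, strain)] = (model, p)
            aucs[strain] = _noiseless_auc(model, p, t)
            for rep in range(1, n_replicates + 1):
                curves.append(
                    simulate_pm_curve(
                        model, p, t_grid=t, noise_sd=noise_sd,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        strain_id=strain, plate_id=plate_id,
                        well_id=f"w{w:02d}", substrate=sub, replicate=rep,
                    )
                )
        s1, s2 = strain_ids
        hi, lo = max(aucs[s1], aucs[s2]), min(aucs[s1], aucs[s2])
        if hi > 0 and (hi - lo) / hi > specificity_rel_diff:
            specific_for[sub] = s1 if aucs[s1] > aucs[s2] else s2
        else:
            specific_for[sub] = "none"

    truth = PlateTruth(substrates, true_params, noise_sd, specific_for, seed)
    return curves, truth
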