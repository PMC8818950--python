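"""Synthetic paired GWAS summary statistics under a known causal model.

Generates exposure/outcome tables with configurable per-SNP pleiotropy,
block LD structure, palindromic alleles, and harmonization corruptions
(allele swaps, strand flips) applied to the emitted outcome table only.
A truth record retains every latent value so downstream modules can be
tested against ground truth without any external data.

Simplifications: observation noise on each beta is independent normal with
sd equal to the emitted standard error (no winner's-curse modeling), and
binary-trait effects are treated as log-odds directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .gwas_io import SummaryStatRecord
from .harmonization import COMPLEMENT
from .instruments import LDMatrix

__all__ = ["SyntheticScenario", "TruthRecord", "generate_pair", "generate_ld_matrix"]

_NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))

#: blocks are spaced far beyond any plausible clumping window
_BLOCK_SPACING_BP = 50_000_000
_WITHIN_BLOCK_SPACING_BP = 1_000


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one paired-table draw."""

    nsnp: int = 50
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    beta_x_sd: float = 0.05
    n_exp: int = 1_000_000
    n_out: int = 20_000
    maf_range: tuple[float, float] = (0.1, 0.4)
    frac_palindromic: float = 0.0
    frac_palindromic_noninferable: float = 0.0
    frac_allele_swapped: float = 0.0
    frac_strand_flipped: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nsnp < 1:
            raise ValueError("nsnp must be >= 1")
        for name in (
            "frac_palindromic",
            "frac_palindromic_noninferable",
            "frac_allele_swapped",
            "frac_strand_flipped",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.beta_x_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        if self.n_exp < 1 or self.n_out < 1:
            raise ValueError("sample sizes must be >= 1")
        total_block = sum(size for size, _ in self.ld_blocks)
        if total_block > self.nsnp:
            raise ValueError("ld_blocks exceed nsnp")
        for size, r2 in self.ld_blocks:
            if size < 1 or not 0.0 <= r2 <= 1.0:
                raise ValueError(f"invalid ld block ({size}, {r2})")


@dataclass
class TruthRecord:
    """Latent values behind one generated table pair."""

    theta: float
    snp_ids: list[str]
    true_beta_x: list[float]
    true_beta_y: list[float]
    pleiotropy: list[float]
    obs_beta_x: list[float]
    #: observed outcome effects in the exposure's allele orientation,
    #: i.e. what harmonization should recover after undoing corruptions
    latent_beta_out: list[float]
    latent_eaf_out: list[float]
    allele_swapped: list[bool]
    strand_flipped: list[bool]
    block_of_snp: list[int]
    scenario: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _block_layout(scenario: SyntheticScenario) -> list[int]:
    """Block id per SNP: declared blocks fill the front, remainder are singletons."""
    blocks: list[int] = []
    bid = 0
    for size, _ in scenario.ld_blocks:
        blocks.extend([bid] * size)
        bid += 1
    while len(blocks) < scenario.nsnp:
        blocks.append(bid)
        bid += 1
    return blocks


def _positions(block_of_snp: Sequence[int]) -> tuple[list[str], list[int]]:
    chroms, positions, seen_in_block = [], [], {}
    for bid in block_of_snp:
        k = seen_in_block.get(bid, 0)
        seen_in_block[bid] = k + 1
        chroms.append(str(bid % 22 + 1))
        positions.append(1_000_000 + bid * _BLOCK_SPACING_BP + k * _WITHIN_BLOCK_SPACING_BP)
    return chroms, positions


def _gwas_se(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def generate_pair(
    scenario: SyntheticScenario,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], TruthRecord]:
    """Draw one exposure table, one outcome table, and their truth record.

    Deterministic given the scenario (the seed lives inside it); the emitted
    exposure table is uncorrupted while the outcome table carries the
    configured allele-swap and strand-flip corruptions.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.nsnp
    snp_ids = [f"rs{1000 + i}" for i in range(n)]
    block_of_snp = _block_layout(scenario)
    chroms, positions = _positions(block_of_snp)

    n_pal = int(round(scenario.frac_palindromic * n))
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist()) if n_pal else set()
    n_noninf = int(round(scenario.frac_palindromic_noninferable * n_pal))
    pal_list = sorted(pal_idx)
    noninf_idx = set(pal_list[:n_noninf])  # deterministic share of the palindromic set

    alleles: list[tuple[str, str]] = []
    eaf = np.empty(n)
    lo, hi = scenario.maf_range
    block_alleles: dict[int, tuple[str, str]] = {}
    for i in range(n):
        pair = block_alleles.get(block_of_snp[i])
        if pair is None:
            if i in pal_idx:
                pair = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
            else:
                pair = _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
            # block mates share an allele pair so an LD proxy stays harmonizable
            block_alleles[block_of_snp[i]] = pair
        alleles.append(pair)
        if set(pair) in ({"A", "T"}, {"G", "C"}):
            if i in noninf_idx:
                # MAF deliberately above the 0.42 inference limit
                eaf[i] = rng.uniform(0.45, 0.55)
            else:
                maf = rng.uniform(lo, min(hi, 0.40))
                eaf[i] = maf if rng.random() < 0.5 else 1.0 - maf
        else:
            maf = rng.uniform(lo, hi)
            eaf[i] = maf if rng.random() < 0.5 else 1.0 - maf

    # half-normal: true exposure effects oriented positive, so "directional"
    # pleiotropy means directional relative to the instrument orientation
    true_bx = (
        np.abs(rng.normal(0.0, scenario.beta_x_sd, size=n))
        if scenario.beta_x_sd > 0
        else np.zeros(n)
    )
    se_x = _gwas_se(scenario.n_exp, eaf)
    obs_bx = true_bx + rng.normal(0.0, 1.0, size=n) * se_x

    if scenario.pleiotropy_sd > 0:
        alpha = rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=n)
    else:
        alpha = np.full(n, scenario.pleiotropy_mean)
    true_by = scenario.theta * true_bx + alpha
    se_y = _gwas_se(scenario.n_out, eaf)
    obs_by = true_by + rng.normal(0.0, 1.0, size=n) * se_y

    p_x = 2.0 * stats.norm.sf(np.abs(obs_bx) / se_x)
    p_y = 2.0 * stats.norm.sf(np.abs(obs_by) / se_y)

    swap_mask = rng.random(n) < scenario.frac_allele_swapped
    strand_mask = rng.random(n) < scenario.frac_strand_flipped

    exposure: list[SummaryStatRecord] = []
    outcome: list[SummaryStatRecord] = []
    for i in range(n):
        a1, a2 = alleles[i]
        exposure.append(
            SummaryStatRecord(
                snp_id=snp_ids[i],
                chrom=chroms[i],
                pos=positions[i],
                effect_allele=a1,
                other_allele=a2,
                eaf=float(eaf[i]),
                beta=float(obs_bx[i]),
                se=float(se_x[i]),
                pval=float(p_x[i]),
                n=scenario.n_exp,
            )
        )
        o_a1, o_a2 = a1, a2
        o_beta, o_eaf = float(obs_by[i]), float(eaf[i])
        if swap_mask[i]:
            o_a1, o_a2 = o_a2, o_a1
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        if strand_mask[i]:
            # purely notational: same physical allele reported on the other
            # strand, so beta and frequency are untouched
            o_a1, o_a2 = COMPLEMENT[o_a1], COMPLEMENT[o_a2]
        outcome.append(
            SummaryStatRecord(
                snp_id=snp_ids[i],
                chrom=chroms[i],
                pos=positions[i],
                effect_allele=o_a1,
                other_allele=o_a2,
                eaf=o_eaf,
                beta=o_beta,
                se=float(se_y[i]),
                pval=float(p_y[i]),
                n=scenario.n_out,
            )
        )

    truth = TruthRecord(
        theta=scenario.theta,
        snp_ids=snp_ids,
        true_beta_x=true_bx.tolist(),
        true_beta_y=true_by.tolist(),
        pleiotropy=alpha.tolist(),
        obs_beta_x=obs_bx.tolist(),
        latent_beta_out=obs_by.tolist(),
        latent_eaf_out=eaf.tolist(),
        allele_swapped=swap_mask.tolist(),
        strand_flipped=strand_mask.tolist(),
        block_of_snp=block_of_snp,
        scenario=asdict(scenario),
    )
    return exposure, outcome, truth


def generate_ld_matrix(scenario: SyntheticScenario) -> LDMatrix:
    """Block-diagonal r² consistent with :func:`generate_pair`'s layout."""
    n = scenario.nsnp
    snp_ids = [f"rs{1000 + i}" for i in range(n)]
    block_of_snp = _block_layout(scenario)
    r2_of_block = {bid: r2 for bid, (_, r2) in enumerate(scenario.ld_blocks)}
    ld = LDMatrix(snp_ids=list(snp_ids))
    for i in range(n):
        for j in range(i + 1, n):
            if block_of_snp[i] == block_of_snp[j]:
                ld.set_r2(snp_ids[i], snp_ids[j], r2_of_block.get(block_of_snp[i], 0.0))
            else:
                ld.set_r2(snp_ids[i], snp_ids[j], 0.0)
    return ld


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    Path(path).write_text(truth.to_json(indent=2))
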