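"""Seeded synthetic benchmark inputs with known ground truth.

The generator emulates the statistical structure the pipeline assumes in real
data, at desk scale:

* a planted-partition (stochastic block model) PPI network — genes are split
  into blocks, within-block pairs interact with probability ``p_in`` and
  cross-block pairs with ``p_out``;
* block-structured co-expression — each block has a latent per-sample factor;
  gene g in block b has log2-scale signal ``sqrt(rho) * factor_b +
  sqrt(1 - rho) * noise``, so within-block Pearson correlation of log values
  is ``rho_within`` in expectation (exactly, at noise_sd = 1) and cross-block
  correlation is 0. Values are emitted on a raw FPKM-like scale
  (2^(5 + 1.5 z) - 1, clipped at 0) so the pipeline's own log2(x+1)
  preprocessing is exercised and recovers an affine image of the signal;
* planted disease modules — a subset of blocks is designated "disease";
  seed CAGs are sampled from those blocks, and the remaining disease-block
  genes are the positives a good ranking should recover.

All generators are pure functions of their parameters and a seed; a master
seed derives independent per-stage sub-seeds so regenerating one input does
not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .net_io import (EdgeList, ExpressionMatrix, GeneSet, write_edge_list,
                     write_expression, write_gene_set)

# log2-scale location and spread of the emitted FPKM-like values
_LOG2_MEAN = 5.0
_LOG2_SD = 1.5


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic instance (block labels, disease modules, seeds)."""

    block_labels: dict[str, int]
    disease_blocks: set[int]
    seed_cags: GeneSet | None = None
    generator_params: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.block_labels)

    def block_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, b in self.block_labels.items():
            out.setdefault(b, []).append(g)
        return out

    def disease_genes(self) -> frozenset[str]:
        return frozenset(g for g, b in self.block_labels.items()
                         if b in self.disease_blocks)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_labels": self.block_labels,
            "disease_blocks": sorted(self.disease_blocks),
            "seed_cags": sorted(self.seed_cags.symbols) if self.seed_cags else [],
            "generator_params": self.generator_params,
        }
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with Path(path).open() as fh:
            payload = json.load(fh)
        seeds = payload.get("seed_cags") or []
        return cls(
            block_labels={str(g): int(b)
                          for g, b in payload["block_labels"].items()},
            disease_blocks=set(payload["disease_blocks"]),
            seed_cags=GeneSet(frozenset(seeds), label="CAG") if seeds else None,
            generator_params=payload.get("generator_params", {}),
        )


def derive_subseeds(master_seed: int, k: int) -> list[int]:
    """Deterministic per-stage sub-seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def generate_network(n_genes: int, n_blocks: int, p_in: float, p_out: float,
                     seed: int, n_disease_blocks: int = 1
                     ) -> tuple[EdgeList, SyntheticTruth]:
    """Planted-partition PPI network with gene names G0000..G{n-1}.

    Blocks are contiguous, near-equal gene ranges; the first
    ``n_disease_blocks`` blocks are designated disease modules.
    """
    if not n_genes >= n_blocks >= 1:
        raise InputError(f"need n_genes >= n_blocks >= 1, "
                         f"got {n_genes}, {n_blocks}")
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise InputError(f"need 0 <= p_out <= p_in <= 1, got "
                         f"p_in={p_in}, p_out={p_out}")
    if not 1 <= n_disease_blocks <= n_blocks:
        raise InputError(f"n_disease_blocks must be in [1, {n_blocks}]")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes - 1)))
    names = [f"G{i:0{width}d}" for i in range(n_genes)]
    labels = np.zeros(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(n_genes), n_blocks)):
        labels[chunk] = b
    ii, jj = np.triu_indices(n_genes, k=1)
    prob = np.where(labels[ii] == labels[jj], p_in, p_out)
    picked = rng.random(len(ii)) < prob
    edges = frozenset((names[i], names[j])
                      for i, j in zip(ii[picked], jj[picked]))
    truth = SyntheticTruth(
        block_labels={names[i]: int(labels[i]) for i in range(n_genes)},
        disease_blocks=set(range(n_disease_blocks)),
        generator_params={"n_genes": n_genes, "n_blocks": n_blocks,
                          "p_in": p_in, "p_out": p_out,
                          "n_disease_blocks": n_disease_blocks,
                          "network_seed": seed},
    )
    return EdgeList(edges), truth


def generate_expression(truth: SyntheticTruth, n_samples: int = 100,
                        rho_within: float = 0.7, noise_sd: float = 1.0,
                        seed: int = 0) -> ExpressionMatrix:
    """Raw-scale expression with block-diagonal correlation structure."""
    if not 0.0 <= rho_within < 1.0:
        raise InputError(f"rho_within must be in [0, 1), got {rho_within}")
    if n_samples < 10:
        raise InputError(f"n_samples must be >= 10, got {n_samples}")
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    labels = np.array([truth.block_labels[g] for g in genes])
    n_blocks = labels.max() + 1
    factors = rng.standard_normal((n_blocks, n_samples))
    noise = rng.standard_normal((len(genes), n_samples)) * noise_sd
    z = np.sqrt(rho_within) * factors[labels] + np.sqrt(1.0 - rho_within) * noise
    raw = np.maximum(np.exp2(_LOG2_MEAN + _LOG2_SD * z) - 1.0, 0.0)
    df = pd.DataFrame(raw, index=genes,
                      columns=[f"S{j:04d}" for j in range(n_samples)])
    truth.generator_params.update({"n_samples": n_samples,
                                   "rho_within": rho_within,
                                   "noise_sd": noise_sd,
                                   "expression_seed": seed})
    return ExpressionMatrix(df, transformed=False)


def plant_cags(truth: SyntheticTruth, per_block: int, seed: int = 0) -> GeneSet:
    """Sample ``per_block`` seed genes uniformly from each disease block."""
    if per_block < 1:
        raise InputError(f"per_block must be >= 1, got {per_block}")
    members = truth.block_members()
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for b in sorted(truth.disease_blocks):
        pool = sorted(members.get(b, []))
        if per_block > len(pool):
            raise InputError(
                f"per_block={per_block} exceeds disease block {b} "
                f"size {len(pool)}"
            )
        chosen.update(rng.choice(pool, size=per_block, replace=False))
    return GeneSet(frozenset(chosen), label="CAG")


@dataclass
class SyntheticBundle:
    """One complete synthetic instance: all three pipeline inputs plus truth."""

    edge_list: EdgeList
    expression: ExpressionMatrix
    cags: GeneSet
    truth: SyntheticTruth


def generate_all(n_genes: int = 300, n_blocks: int = 6, p_in: float = 0.3,
                 p_out: float = 0.02, n_disease_blocks: int = 2,
                 n_samples: int = 100, rho_within: float = 0.7,
                 noise_sd: float = 1.0, cags_per_block: int = 3,
                 seed: int = 0) -> SyntheticBundle:
    """Generate a full instance from one master seed.

    Defaults describe the standard benchmark condition: 300 genes in 6 blocks
    (2 disease modules), moderately dense within-block interactions
    (p_in = 0.3 vs p_out = 0.02), 100 samples with within-block co-expression
    rho = 0.7, and 3 seed CAGs per disease block.
    """
    s_net, s_expr, s_cag = derive_subseeds(seed, 3)
    edge_list, truth = generate_network(
        n_genes, n_blocks, p_in, p_out, seed=s_net,
        n_disease_blocks=n_disease_blocks,
    )
    expr = generate_expression(truth, n_samples=n_samples,
                               rho_within=rho_within, noise_sd=noise_sd,
                               seed=s_expr)
    cags = plant_cags(truth, per_block=cags_per_block, seed=s_cag)
    truth.seed_cags = cags
    truth.generator_params.update({"cags_per_block": cags_per_block,
                                   "master_seed": seed})
    return SyntheticBundle(edge_list, expr, cags, truth)


def write_inputs(bundle: SyntheticBundle, out_dir: str | Path
                 ) -> dict[str, Path]:
    """Write ppi.tsv, expression.tsv, cags.txt and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out / "ppi.tsv",
        "expression": out / "expression.tsv",
        "cags": out / "cags.txt",
        "truth": out / "truth.json",
    }
    write_edge_list(bundle.edge_list, paths["ppi"])
    write_expression(bundle.expression, paths["expression"])
    write_gene_set(bundle.cags, paths["cags"])
    bundle.truth.to_json(paths["truth"])
    return paths
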