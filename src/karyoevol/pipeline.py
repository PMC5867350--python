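"""End-to-end analysis pipeline and command-line interface.

Each analysis stage is exposed both as a plain function returning the
module-level objects (so the CLI is a thin shell over the library) and as
a click subcommand writing TSV/newick outputs plus a JSON provenance block
recording the configuration, seeds, and conventions used.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
import scipy

from . import __version__, datasets
from .ancestral import blomberg_k, bm_ancestral_states, pagel_lambda
from .chromevol import (
    ModelFamily,
    expected_events,
    joint_ancestral_states,
    marginal_ancestral_states,
    select_model,
)
from .karyotypes import (
    Sex,
    divergence_matrix,
    read_karyotype_table,
    select_by_sex,
    write_karyotype_table,
)
from .phylo import grafen_lengths, prune_to_taxa, read_newick, upgma, write_newick
from .rearrange import annotate_tree_events, write_branch_events
from .synth import fabricate_karyotype_table, random_yule_tree, simulate_bm

logger = logging.getLogger(__name__)

EXIT_INPUT = 2
EXIT_NONCONVERGENCE = 3


@dataclass
class PipelineConfig:
    karyotype_table_path: str | None = None  # None = packaged fixture
    tree_path: str | None = None
    sex_preference: str = "female"
    signal_permutations: int = 1000
    seed: int = 1
    ctmc_families: tuple[str, ...] = tuple(f.value for f in ModelFamily)
    n_restarts: int = 10
    n_maps: int = 300
    root_prior: str = "weighted"
    output_dir: str = "karyoevol_out"


def _load_inputs(config: PipelineConfig):
    if config.karyotype_table_path:
        records = read_karyotype_table(config.karyotype_table_path)
    else:
        records = datasets.load_karyotypes()
    if config.tree_path:
        tree = read_newick(Path(config.tree_path))
    else:
        tree = datasets.load_topology()
    return records, tree


def _analysis_tree(tree, tip_values):
    """Prune to tips with data and apply Grafen lengths (root depth 1)."""
    keep = [n for n in tree.leaf_names if n in tip_values]
    if set(keep) != set(tree.leaf_names):
        tree = prune_to_taxa(tree, keep)
    return grafen_lengths(tree, rho=1.0)


def _write_provenance(outdir: Path, stage: str, config: PipelineConfig, extra: dict) -> None:
    block = {
        "stage": stage,
        "karyoevol_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config": asdict(config),
        **extra,
    }
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(block, indent=2) + "\n")


# --- stage functions ------------------------------------------------------


def run_divergence(config: PipelineConfig):
    """Divergence matrix + UPGMA phenogram from the karyotype table."""
    records, _ = _load_inputs(config)
    chosen = select_by_sex(records, preference=Sex(config.sex_preference))
    matrix = divergence_matrix(chosen)
    phenogram = upgma(matrix)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(outdir / "divergence_matrix.tsv")
    matrix.to_phylip(outdir / "divergence_matrix.phy")
    write_newick(phenogram, outdir / "upgma_phenogram.nwk")
    _write_provenance(
        outdir,
        "divergence",
        config,
        {"conventions": {"index_units": "chromosome-pair changes (raw, not percent)",
                         "fn": "2n + biarmed", "sex": config.sex_preference}},
    )
    return matrix, phenogram


def run_asr(config: PipelineConfig):
    """Brownian-motion ancestral states + phylogenetic signal statistics."""
    records, tree = _load_inputs(config)
    tips = {r.species_name: float(r.diploid_number)
            for r in select_by_sex(records, preference=Sex(config.sex_preference))}
    if not config.karyotype_table_path:
        tips.update({k: float(v) for k, v in datasets.load_outgroup_diploids().items()})
    tree = _analysis_tree(tree, tips)
    tips = {k: v for k, v in tips.items() if k in tree.leaf_names}

    estimates, sigma2 = bm_ancestral_states(tree, tips)
    lam, lam_ll, lam_p = pagel_lambda(tree, tips)
    k_stat, k_p = blomberg_k(
        tree, tips, n_permutations=config.signal_permutations, seed=config.seed
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "node": e.node_id,
                "estimate": e.estimate,
                "variance": e.variance,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
            }
            for e in estimates
        ]
    ).to_csv(outdir / "ancestral_states_bm.tsv", sep="\t", index=False, float_format="%.6f")
    signal = {
        "lambda_hat": lam,
        "lambda_logL": lam_ll,
        "lambda_p": lam_p,
        "k_stat": k_stat,
        "k_p": k_p,
        "n_permutations": config.signal_permutations,
        "seed": config.seed,
        "sigma2_hat": sigma2,
    }
    pd.Series(signal).to_csv(outdir / "signal_report.tsv", sep="\t", header=False)
    _write_provenance(outdir, "asr", config, {"signal": signal})
    return estimates, sigma2, signal


def run_chromevol(config: PipelineConfig):
    """CTMC model selection, ancestral states, and branch events."""
    records, tree = _load_inputs(config)
    chosen = select_by_sex(records, preference=Sex(config.sex_preference))
    diploids = {r.species_name: r.diploid_number for r in chosen}
    outgroups: dict[str, int] = {}
    if not config.karyotype_table_path:
        outgroups = datasets.load_outgroup_diploids()
        diploids.update(outgroups)
    odd = sorted(k for k, v in diploids.items() if v % 2)
    if odd:
        raise ValueError(f"odd diploid numbers for {odd}; select the female complement")
    haploids = {k: v // 2 for k, v in diploids.items()}
    tree = _analysis_tree(tree, haploids)
    haploids = {k: v for k, v in haploids.items() if k in tree.leaf_names}

    families = [ModelFamily(f) for f in config.ctmc_families]
    fits, best = select_model(
        tree,
        haploids,
        families,
        n_restarts=config.n_restarts,
        seed=config.seed,
        root=config.root_prior,
    )
    if not best.converged:
        raise RuntimeError(f"best model {best.spec.family.value} did not converge")
    marginal = marginal_ancestral_states(tree, haploids, best, root=config.root_prior)
    joint = joint_ancestral_states(tree, haploids, best, root=config.root_prior)
    table, totals = expected_events(
        tree, haploids, best, n_maps=config.n_maps, seed=config.seed, root=config.root_prior
    )
    events = annotate_tree_events(tree, joint, chosen, tip_diploids=outgroups)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "family": f.spec.family.value,
                "logL": round(f.logL, 6),
                "AIC": round(f.aic, 6),
                "k": f.spec.k,
                "converged": f.converged,
                "best": f is best,
                **{name: f.rates[name] for name in f.spec.parameter_names},
            }
            for f in fits
        ]
    ).to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "node": a.node_id,
                "best_haploid": a.best_haploid,
                "best_diploid": a.best_diploid,
                "joint_haploid": joint[a.node_id],
                "joint_diploid": 2 * joint[a.node_id],
                "posterior_max": round(float(a.posterior.max()), 6),
            }
            for a in marginal
        ]
    ).to_csv(outdir / "ancestral_states_ctmc.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "child_node": b.branch_id,
                "expected_fissions": round(b.expected_gains, 4),
                "expected_fusions": round(b.expected_losses, 4),
                "mc_error": round(b.mc_error, 4),
            }
            for b in table
        ]
    ).to_csv(outdir / "expected_events.tsv", sep="\t", index=False)
    write_branch_events(events, outdir / "branch_events.tsv")
    _write_provenance(
        outdir,
        "chromevol",
        config,
        {
            "best_family": best.spec.family.value,
            "totals": totals,
            "conventions": {
                "terminology": "gains reported as fissions, losses as fusions",
                "root_prior": config.root_prior,
                "state_bounds": [best.spec.n_min, best.spec.n_max],
                "node_values": "joint (max-product) states drive branch events",
            },
        },
    )
    return fits, best, marginal, joint, table, totals, events


def run_simulate(config: PipelineConfig, n_species: int = 12, n_tips: int = 12):
    """Write a synthetic karyotype table, Yule tree, and Brownian traits."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = fabricate_karyotype_table(n_species, seed=config.seed)
    write_karyotype_table(records, outdir / "synthetic_karyotypes.tsv")
    tree = random_yule_tree(n_tips, seed=config.seed)
    write_newick(tree, outdir / "synthetic_tree.nwk")
    traits = simulate_bm(tree, sigma2=25.0, root_value=48.0, seed=config.seed)
    pd.Series(traits).to_csv(
        outdir / "synthetic_traits.tsv", sep="\t", header=["diploid_number"], index_label="species"
    )
    _write_provenance(outdir, "simulate", config, {"n_species": n_species, "n_tips": n_tips})
    return records, tree, traits


# --- CLI ------------------------------------------------------------------


def _common(func):
    func = click.option("--karyotypes", type=click.Path(exists=True), default=None,
                        help="Karyotype TSV (default: packaged compilation).")(func)
    func = click.option("--tree", type=click.Path(exists=True), default=None,
                        help="Newick tree (default: packaged topology).")(func)
    func = click.option("--sex", type=click.Choice(["female", "male"]), default="female",
                        help="Complement used for sex-dimorphic species.")(func)
    func = click.option("--seed", type=int, default=1, show_default=True)(func)
    func = click.option("--out", type=click.Path(), default="karyoevol_out", show_default=True)(func)
    return func


def _config(karyotypes, tree, sex, seed, out, **kw) -> PipelineConfig:
    return PipelineConfig(
        karyotype_table_path=karyotypes,
        tree_path=tree,
        sex_preference=sex,
        seed=seed,
        output_dir=out,
        **kw,
    )


def _run(stage, config):
    try:
        return stage(config)
    except (ValueError, KeyError, FileNotFoundError) as exc:
        click.echo(f"input error: {exc}", err=True)
        sys.exit(EXIT_INPUT)
    except RuntimeError as exc:
        click.echo(f"numerical failure: {exc}", err=True)
        sys.exit(EXIT_NONCONVERGENCE)


@click.group()
def cli():
    """Karyotype divergence and chromosome-number evolution analyses."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@_common
def divergence(karyotypes, tree, sex, seed, out):
    """Pairwise karyotype divergence matrix and UPGMA phenogram."""
    matrix, _ = _run(run_divergence, _config(karyotypes, tree, sex, seed, out))
    click.echo(f"wrote divergence matrix for {len(matrix.taxa)} taxa to {out}")


@cli.command(name="upgma")
@click.option("--matrix", "matrix_path", type=click.Path(exists=True), required=True,
              help="Square divergence-matrix TSV (taxa as first row/column).")
@click.option("--euclidean-rows", is_flag=True,
              help="Cluster Euclidean distances between matrix rows instead.")
@click.option("--out", type=click.Path(), default="karyoevol_out", show_default=True)
def upgma_cmd(matrix_path, euclidean_rows, out):
    """UPGMA phenogram from a precomputed divergence matrix."""
    from .karyotypes import DivergenceMatrix

    def stage(_):
        matrix = DivergenceMatrix.from_tsv(matrix_path)
        tree = upgma(matrix, euclidean_rows=euclidean_rows)
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        write_newick(tree, outdir / "upgma_phenogram.nwk")
        return tree

    _run(stage, None)
    click.echo(f"phenogram written to {out}")


@cli.command()
@_common
@click.option("--permutations", type=int, default=1000, show_default=True)
def asr(karyotypes, tree, sex, seed, out, permutations):
    """Brownian-motion ancestral diploid numbers with signal statistics."""
    cfg = _config(karyotypes, tree, sex, seed, out, signal_permutations=permutations)
    estimates, sigma2, signal = _run(run_asr, cfg)
    click.echo(
        f"root estimate {estimates[0].estimate:.3f} (sigma2={sigma2:.3f}); "
        f"lambda={signal['lambda_hat']:.3f} (p={signal['lambda_p']:.2e}), "
        f"K={signal['k_stat']:.3f} (p={signal['k_p']:.4f})"
    )


@cli.command()
@_common
@click.option("--permutations", type=int, default=1000, show_default=True)
def signal(karyotypes, tree, sex, seed, out, permutations):
    """Phylogenetic signal (Pagel's lambda, Blomberg's K) only."""
    cfg = _config(karyotypes, tree, sex, seed, out, signal_permutations=permutations)
    _, _, stats = _run(run_asr, cfg)
    click.echo(
        f"lambda={stats['lambda_hat']:.3f} p={stats['lambda_p']:.2e}; "
        f"K={stats['k_stat']:.3f} p={stats['k_p']:.4f}"
    )


@cli.command()
@_common
@click.option("--families", default=",".join(f.value for f in ModelFamily),
              help="Comma-separated model families to fit.")
@click.option("--restarts", type=int, default=10, show_default=True)
@click.option("--maps", type=int, default=300, show_default=True,
              help="Stochastic maps for expected event counts.")
def chromevol(karyotypes, tree, sex, seed, out, families, restarts, maps):
    """CTMC model selection, ancestral states, and branch events."""
    cfg = _config(
        karyotypes, tree, sex, seed, out,
        ctmc_families=tuple(families.split(",")),
        n_restarts=restarts,
        n_maps=maps,
    )
    fits, best, marginal, joint, table, totals, events = _run(run_chromevol, cfg)
    click.echo(f"best model: {best.spec.family.value} (AIC {best.aic:.2f})")
    click.echo(
        f"total expected fusions {totals['total_losses']:.2f} "
        f"(fissions {totals['total_gains']:.2f})"
    )


@cli.command()
@_common
@click.option("--families", default=",".join(f.value for f in ModelFamily))
@click.option("--restarts", type=int, default=10, show_default=True)
@click.option("--maps", type=int, default=300, show_default=True)
def events(karyotypes, tree, sex, seed, out, families, restarts, maps):
    """Branch-level fusion/fission/inversion table (runs the CTMC stage)."""
    cfg = _config(
        karyotypes, tree, sex, seed, out,
        ctmc_families=tuple(families.split(",")),
        n_restarts=restarts,
        n_maps=maps,
    )
    *_, branch_events = _run(run_chromevol, cfg)
    n = sum(1 for e in branch_events if e.fusions or e.fissions)
    click.echo(f"{n} branches carry chromosome-number changes; table in {out}")


@cli.command()
@_common
@click.option("--n-species", type=int, default=12, show_default=True)
@click.option("--n-tips", type=int, default=12, show_default=True)
def simulate(karyotypes, tree, sex, seed, out, n_species, n_tips):
    """Generate a synthetic karyotype table, Yule tree, and traits."""
    cfg = _config(karyotypes, tree, sex, seed, out)
    _run(lambda c: run_simulate(c, n_species=n_species, n_tips=n_tips), cfg)
    click.echo(f"synthetic data written to {out}")


@cli.command(name="all")
@_common
@click.option("--permutations", type=int, default=1000, show_default=True)
@click.option("--restarts", type=int, default=10, show_default=True)
@click.option("--maps", type=int, default=300, show_default=True)
def run_all(karyotypes, tree, sex, seed, out, permutations, restarts, maps):
    """Run every stage of the pipeline (fixtures by default)."""
    cfg = _config(karyotypes, tree, sex, seed, out, signal_permutations=permutations)
    _run(run_divergence, cfg)
    _run(run_asr, cfg)
    cfg2 = _config(karyotypes, tree, sex, seed, out, n_restarts=restarts, n_maps=maps)
    _run(run_chromevol, cfg2)
    click.echo(f"full pipeline outputs in {out}")


if __name__ == "__main__":
    cli()
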