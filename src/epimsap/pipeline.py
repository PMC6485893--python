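"""End-to-end MSAP analysis: read -> QC -> states -> statistics -> report.

One :func:`run_pipeline` call takes paired score matrices plus sample
metadata and produces, per genotype x primer combination: the MSL/NML
partition, methylation-state frequency table, Phi_PT / Phi_ST tables with
permutation p-values, Shannon-diversity summaries, the differential-
methylation locus list, UPGMA dendrograms (Newick) and categorical
heatmaps, plus ordination coordinates and a run manifest.  Everything is a
pure function of (inputs, config, seed): one global seed is fanned out to
deterministic per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova_two_group, pairwise_distance, pcoa, pca
from .diffmeth import heatmap_export, test_all_msl, upgma
from .diversity import group_diversity, paired_t, wilcoxon_rank_sum
from .io_profiles import (
    PairedProfile,
    metadata_frame,
    pair_profiles,
    read_metadata,
    read_score_matrix,
)
from .marker_qc import primer_qc_report, replicate_pairs
from .meth_states import (
    MethylationStateMatrix,
    call_states,
    partition_loci,
    recode_msl_binary,
    recode_nml_binary,
    state_frequencies,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run."""

    score_paths: Mapping  # (enzyme, primer) -> path
    metadata_path: str
    outdir: str
    error_rate: float = 0.05        # MSL discordance threshold
    fdr: float = 0.05
    n_perm: int = 9999
    seed: int | None = None
    uninformative_policy: str = "fully_methylated"
    bh_family: str = "per-primer"   # or "pooled"
    heatmap_loci: str = "significant"  # or "all-msl"
    dm_binary: bool = False
    make_plots: bool = True

    def param_hash(self) -> str:
        payload = {
            k: ({str(kk): str(vv) for kk, vv in v.items()} if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir"
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int | None, name: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    entropy = [0 if seed is None else int(seed), zlib.crc32(name.encode())]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the result tables and writes artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "epimsap",
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": [],
        "warnings": [],
    }
    results: dict = {}

    def stage(name: str):
        def deco(fn):
            try:
                value = fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
            return value
        return deco

    @stage("read_inputs")
    def _inputs():
        records = read_metadata(config.metadata_path)
        primers = sorted({p for (_, p) in config.score_paths})
        profiles = {}
        for primer in primers:
            hpa = read_score_matrix(config.score_paths[("HpaII", primer)], "HpaII", primer)
            msp = read_score_matrix(config.score_paths[("MspI", primer)], "MspI", primer)
            profiles[primer] = pair_profiles(hpa, msp)
        return records, profiles

    records, profiles = _inputs
    meta = metadata_frame(records)
    core = meta[meta.replicate_of.isna()]
    genotypes = sorted(core.genotype.unique())

    @stage("marker_qc")
    def _qc():
        pairs = replicate_pairs(records)
        if not pairs:
            return None
        rows = []
        for primer, profile in profiles.items():
            groups = meta.propagation.to_dict()
            rep = primer_qc_report(profile.hpa, profile.msp, pairs, groups)
            rows.append(rep.to_frame())
        table = pd.concat(rows, ignore_index=True)
        _write(table, out / "primer_qc.tsv")
        return table

    results["qc"] = _qc

    states_by_primer: dict[str, MethylationStateMatrix] = {}
    partitions: dict[str, object] = {}

    @stage("methylation_states")
    def _states():
        part_rows = []
        for primer, profile in profiles.items():
            states = call_states(profile)
            part = partition_loci(states, error_rate=config.error_rate)
            states_by_primer[primer] = states
            partitions[primer] = part
            states.values.to_csv(
                out / f"states_{primer}.tsv", sep="\t", na_rep="NA", lineterminator="\n"
            )
            part_rows.append(
                pd.DataFrame(
                    {
                        "primer": primer,
                        "locus_id": part.discordance.index,
                        "class": [
                            "MSL" if l in set(part.msl_ids) else "NML"
                            for l in part.discordance.index
                        ],
                        "discordance_freq": part.discordance.to_numpy(),
                    }
                )
            )
        table = pd.concat(part_rows, ignore_index=True)
        _write(table, out / "locus_partition.tsv")
        return table

    results["partition"] = _states

    @stage("state_frequencies")
    def _freqs():
        tables = []
        for primer, states in states_by_primer.items():
            ids = [s for s in states.samples if s in core.index]
            sub = MethylationStateMatrix(states.values.loc[ids], primer)
            groups = core.loc[ids, "propagation"].to_dict()
            tbl = state_frequencies(sub, partitions[primer], groups)
            tbl.insert(0, "primer", primer)
            tables.append(tbl.reset_index())
        table = pd.concat(tables, ignore_index=True)
        _write(table, out / "state_frequencies.tsv")
        return table

    results["state_frequencies"] = _freqs

    @stage("diversity")
    def _diversity():
        per_locus_rows, summary_rows = [], []
        si_pairs: list[tuple[float, float]] = []
        for primer, states in states_by_primer.items():
            part = partitions[primer]
            profile = profiles[primer]
            msl_bin_all = recode_msl_binary(states, part, config.uninformative_policy)
            nml_bin_all = recode_nml_binary(profile, part)
            for geno in genotypes:
                ids = core.index[core.genotype == geno]
                groups = core.loc[ids, "propagation"].to_dict()
                for cls, block in (("MSL", msl_bin_all), ("NML", nml_bin_all)):
                    if block.shape[1] == 0:
                        continue
                    per_locus, means = group_diversity(block.loc[ids], groups)
                    pooled_freq = block.loc[ids].mean(axis=0, skipna=True)
                    for grp in per_locus.columns:
                        for locus in per_locus.index:
                            per_locus_rows.append(
                                {
                                    "primer": primer, "genotype": geno, "class": cls,
                                    "group": grp, "locus_id": locus,
                                    "shannon": per_locus.loc[locus, grp],
                                }
                            )
                    from .diversity import shannon_locus
                    s_pooled = pd.Series(
                        shannon_locus(pooled_freq.to_numpy()), index=pooled_freq.index
                    )
                    summary_rows.append(
                        {
                            "primer": primer, "genotype": geno, "class": cls,
                            "n_loci": block.shape[1],
                            "SI": float(s_pooled.mean()),
                            "SI_field": float(means.get("field", np.nan)),
                            "SI_micro": float(means.get("micro", np.nan)),
                        }
                    )
        per_locus_df = pd.DataFrame(per_locus_rows)
        summary = pd.DataFrame(summary_rows)

        # field-vs-micro Wilcoxon on per-locus S within each class, and
        # MSL-vs-NML Wilcoxon on pooled per-locus S, both reported
        tests = []
        for (primer, geno), blk in summary.groupby(["primer", "genotype"]):
            sub = per_locus_df[(per_locus_df.primer == primer) & (per_locus_df.genotype == geno)]
            for cls in ("MSL", "NML"):
                fx = sub[(sub["class"] == cls) & (sub.group == "field")].shannon.dropna()
                mx = sub[(sub["class"] == cls) & (sub.group == "micro")].shannon.dropna()
                if len(fx) and len(mx):
                    w, p = wilcoxon_rank_sum(fx, mx)
                    tests.append(
                        {"primer": primer, "genotype": geno, "comparison": f"{cls}_field_vs_micro",
                         "W": w, "p": p}
                    )
            msl_s = sub[sub["class"] == "MSL"].shannon.dropna()
            nml_s = sub[sub["class"] == "NML"].shannon.dropna()
            if len(msl_s) and len(nml_s):
                w, p = wilcoxon_rank_sum(msl_s, nml_s)
                tests.append(
                    {"primer": primer, "genotype": geno, "comparison": "MSL_vs_NML",
                     "W": w, "p": p}
                )
        # paired t across genotype x primer x group mean SI: MSL vs NML
        piv = summary.pivot_table(index=["primer", "genotype"], columns="class", values="SI")
        if {"MSL", "NML"} <= set(piv.columns) and len(piv) >= 2:
            try:
                t, p = paired_t(piv["MSL"].to_numpy(), piv["NML"].to_numpy())
                tests.append({"primer": "all", "genotype": "all",
                              "comparison": "paired_t_SI_MSL_vs_NML", "W": t, "p": p})
            except ValueError as exc:
                manifest["warnings"].append(f"paired_t skipped: {exc}")
        tests_df = pd.DataFrame(tests)
        _write(per_locus_df, out / "shannon_per_locus.tsv")
        _write(summary, out / "shannon_summary.tsv")
        _write(tests_df, out / "diversity_tests.tsv")
        return {"per_locus": per_locus_df, "summary": summary, "tests": tests_df}

    results["diversity"] = _diversity

    @stage("amova")
    def _amova():
        rows = []
        for primer, profile in profiles.items():
            part = partitions[primer]
            states = states_by_primer[primer]
            msl_bin = recode_msl_binary(states, part, config.uninformative_policy)
            nml_bin = recode_nml_binary(profile, part)
            for geno in genotypes:
                ids = list(core.index[core.genotype == geno])
                groups = core.loc[ids, "propagation"].to_dict()
                jobs = [
                    ("PhiPT", "HpaII", profile.hpa.values.loc[ids]),
                    ("PhiPT", "MspI", profile.msp.values.loc[ids]),
                    ("PhiST", "MSL", msl_bin.loc[ids]),
                    ("PhiST", "NML", nml_bin.loc[ids]),
                ]
                for stat, layer, matrix in jobs:
                    if matrix.shape[1] == 0:
                        continue
                    D = pairwise_distance(matrix, "hamming_sq")
                    res = amova_two_group(
                        D, groups, n_perm=config.n_perm,
                        seed=_stage_seed(config.seed, f"amova:{primer}:{geno}:{stat}:{layer}"),
                    )
                    rows.append(
                        {
                            "primer": primer, "genotype": geno, "statistic": stat,
                            "layer": layer, "n_loci": matrix.shape[1], "phi": res.phi,
                            "p_value": res.p_value, "ss_among": res.ss_among,
                            "ss_within": res.ss_within,
                            "sigma2_among_raw": res.sigma2_among_raw,
                        }
                    )
        table = pd.DataFrame(rows)
        _write(table, out / "amova_phi.tsv")
        return table

    results["amova"] = _amova

    @stage("ordination")
    def _ordination():
        # combined-primer PCoA per enzyme (profiles concatenated locus-wise)
        coords_frames = []
        for enzyme in ("HpaII", "MspI"):
            mats = [
                (p.hpa if enzyme == "HpaII" else p.msp).values
                for p in profiles.values()
            ]
            combined = pd.concat(mats, axis=1)
            combined = combined.loc[[s for s in combined.index if s in core.index]]
            D = pairwise_distance(combined, "hamming_sq")
            ord_ = pcoa(D)
            coords = ord_.coordinates.iloc[:, : min(3, ord_.coordinates.shape[1])].copy()
            coords.insert(0, "enzyme", enzyme)
            coords_frames.append(coords.reset_index(names="sample_id"))
            if config.make_plots:
                _scatter(
                    ord_, core, out / f"pcoa_{enzyme}.png",
                    f"PCoA ({enzyme}, all primers)",
                )
        table = pd.concat(coords_frames, ignore_index=True)
        _write(table, out / "pcoa_coordinates.tsv")
        return table

    results["ordination"] = _ordination

    @stage("differential_methylation")
    def _dm():
        all_dm, heat_meta = [], []
        for primer, states in states_by_primer.items():
            part = partitions[primer]
            for geno in genotypes:
                ids = list(core.index[core.genotype == geno])
                groups = core.loc[ids, "propagation"].to_dict()
                sub = MethylationStateMatrix(states.values.loc[ids], primer)
                dm = test_all_msl(sub, part, groups, fdr=config.fdr, binary=config.dm_binary)
                dm.insert(0, "genotype", geno)
                dm.insert(0, "primer", primer)
                all_dm.append(dm)
                sig = dm.loc[dm.significant, "locus_id"].tolist()
                loci_for_heat = sig if config.heatmap_loci == "significant" else part.msl_ids
                dend = None
                if loci_for_heat:
                    Dg = pairwise_distance(sub.values[loci_for_heat], "gower")
                    dend = upgma(Dg)
                    (out / f"dendrogram_{primer}_{geno}.nwk").write_text(
                        dend.to_newick() + "\n", encoding="utf-8"
                    )
                heatmap_export(
                    sub, loci_for_heat, groups, dend,
                    out / f"heatmap_{primer}_{geno}.tsv",
                    (out / f"heatmap_{primer}_{geno}.png") if (config.make_plots and loci_for_heat) else None,
                )
                heat_meta.append({"primer": primer, "genotype": geno, "n_significant": len(sig)})
        table = pd.concat(all_dm, ignore_index=True)
        if config.bh_family == "pooled":
            from .diffmeth import bh_adjust
            table["q"] = bh_adjust(table["p"].to_numpy())
            table["significant"] = table["q"] < config.fdr
        _write(table, out / "differential_methylation.tsv")
        _write(pd.DataFrame(heat_meta), out / "dm_counts.tsv")
        return table

    results["dm"] = _dm

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    results["manifest"] = manifest
    return results


def _scatter(ordination, core: pd.DataFrame, path: Path, title: str) -> None:
    """Genotype-coloured, propagation-filled ordination scatter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ordination.coordinates
    if coords.shape[1] < 2:
        return
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    palette = ["#1a9641", "#d7191c", "#2c7bb6", "#fdae61", "#984ea3"]
    for gi, geno in enumerate(sorted(core.genotype.unique())):
        for prop, filled in (("field", True), ("micro", False)):
            ids = [
                s for s in coords.index
                if s in core.index
                and core.loc[s, "genotype"] == geno
                and core.loc[s, "propagation"] == prop
            ]
            if not ids:
                continue
            ax.scatter(
                coords.loc[ids].iloc[:, 0], coords.loc[ids].iloc[:, 1],
                s=18, label=f"{geno} {prop}",
                facecolors=palette[gi % len(palette)] if filled else "none",
                edgecolors=palette[gi % len(palette)],
            )
    pv = ordination.percent_variance
    ax.set_xlabel(f"Axis 1 ({pv[0]:.1f}%)")
    ax.set_ylabel(f"Axis 2 ({pv[1]:.1f}%)" if len(pv) > 1 else "Axis 2")
    ax.set_title(title)
    ax.legend(fontsize=6)
    fig.savefig(path, dpi=150)
    plt.close(fig)


_REPORT_SECTIONS = [
    ("Primer QC", "primer_qc.tsv"),
    ("Locus partition (MSL/NML)", "locus_partition.tsv"),
    ("Methylation-state frequencies", "state_frequencies.tsv"),
    ("Shannon diversity", "shannon_summary.tsv"),
    ("Diversity tests", "diversity_tests.tsv"),
    ("AMOVA Phi statistics", "amova_phi.tsv"),
    ("Differential methylation", "dm_counts.tsv"),
]


def report(run_dir: str | Path, path: str | Path | None = None) -> str:
    """Assemble a markdown summary from a pipeline output directory."""
    run_dir = Path(run_dir)
    lines = ["# MSAP analysis report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [
            f"Package epimsap {manifest.get('version')}, seed {manifest.get('seed')}, "
            f"parameter hash `{manifest.get('param_hash')}`.",
            "",
        ]
    for title, fname in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        fpath = run_dir / fname
        if not fpath.exists():
            lines += ["_Artifact missing; section skipped._", ""]
            continue
        df = pd.read_csv(fpath, sep="\t")
        if fname == "dm_counts.tsv":
            total = int(df["n_significant"].sum()) if "n_significant" in df else 0
            if total == 0:
                lines.append("No loci significant at the configured FDR.")
            else:
                lines.append(f"{total} significant loci across genotype/primer families.")
        lines.append("")
        lines.append("```")
        lines.append(df.head(20).to_string(index=False))
        lines.append("```")
        lines.append("")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
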