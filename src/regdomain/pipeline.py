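"""Pipeline orchestration: config-driven runs with provenance and fail-fast validation.

A run config (YAML) names the input files and the stages to execute
(``consensus``, ``venn3``, ``sweep``, ``tad_enrich``, ``motif``).  Every
output table carries a metadata header recording the tool version, a config
hash, the seed, anchor direction and universe sizes, so that counts that
depend on asymmetric choices are auditable; a JSON manifest is written
alongside.  Validation runs before any stage: a missing file or a
chromosome-namespace mismatch aborts the run before any output exists.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .domains import DomainMap, domain_enrichment
from .enrichment import DEFAULT_DISTANCES, GeneIndex, distance_sweep
from .genome import (
    FormatError,
    check_chrom_namespaces,
    read_bed,
    read_chrom_sizes,
    read_cluster,
    read_genes,
    write_bed,
)
from .motifs import PWM, RegionSeqSet, fold_enrichment
from .overlap import consensus, partition_three_way

log = logging.getLogger(__name__)

STAGES = ("consensus", "venn3", "sweep", "tad_enrich", "motif")


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"run config {path} must be a mapping")
    return cfg


def config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p


def validate_inputs(config: Mapping[str, Any], base_dir: str | Path = ".") -> list[Finding]:
    """Pre-flight checks: files exist, BEDs parse, domains don't overlap,
    chromosome namespaces agree, clusters resolve.  Errors abort a run."""
    base = Path(base_dir)
    findings: list[Finding] = []
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        findings.append(Finding("error", f"unknown stages {sorted(unknown)}"))
        return findings

    def need(key_path: str, value: str | None) -> Path | None:
        if value is None:
            findings.append(Finding("error", f"config key {key_path!r} is required"))
            return None
        p = _resolve(base, value)
        if not p.exists():
            findings.append(Finding("error", f"{key_path}: file not found: {p}"))
            return None
        return p

    namespaces: dict[str, set[str]] = {}
    genes = None
    if {"sweep", "tad_enrich"} & set(stages):
        gene_path = need("genes", config.get("genes"))
        sizes_path = need("chrom_sizes", config.get("chrom_sizes"))
        if gene_path:
            try:
                genes = read_genes(gene_path)
                namespaces["genes"] = {g.chrom for g in genes}
            except FormatError as exc:
                findings.append(Finding("error", str(exc)))
        if sizes_path:
            try:
                namespaces["chrom_sizes"] = set(read_chrom_sizes(sizes_path))
            except FormatError as exc:
                findings.append(Finding("error", str(exc)))
        peaks_path = config.get("peaks")
        if peaks_path is None and "consensus" not in stages:
            findings.append(Finding("error", "config key 'peaks' required when no consensus stage runs"))
        elif peaks_path is not None:
            p = need("peaks", peaks_path)
            if p:
                try:
                    namespaces["peaks"] = {iv.chrom for iv in read_bed(p)}
                except FormatError as exc:
                    findings.append(Finding("error", str(exc)))
        for cl in config.get("clusters", []):
            cp = need("clusters", cl)
            if cp and genes is not None:
                try:
                    cluster = read_cluster(cp, (g.gene_id for g in genes))
                    frac = cluster.n_unresolved / max(1, cluster.n_unresolved + len(cluster))
                    if frac > 0.2:
                        findings.append(
                            Finding("warning",
                                    f"cluster {cluster.name}: {cluster.n_unresolved} ids "
                                    f"({100 * frac:.0f}%) not in the gene universe")
                        )
                except FormatError as exc:
                    findings.append(Finding("error", str(exc)))
    if "consensus" in stages:
        c = config.get("consensus", {})
        need("consensus.anchor", c.get("anchor"))
        for i, other in enumerate(c.get("against", []) or [None]):
            need(f"consensus.against[{i}]", other)
    if "venn3" in stages:
        v = config.get("venn3", {})
        sets = v.get("sets", {})
        if len(sets) != 3:
            findings.append(Finding("error", "venn3 needs exactly three labelled peak sets"))
        for label, path in sets.items():
            need(f"venn3.sets.{label}", path)
    if "tad_enrich" in stages:
        for i, dpath in enumerate(config.get("tad_enrich", {}).get("domains", []) or [None]):
            p = need(f"tad_enrich.domains[{i}]", dpath)
            if p:
                try:
                    DomainMap(read_bed(p, kind="domains"))
                except (FormatError, ValueError) as exc:
                    findings.append(Finding("error", f"{p}: {exc}"))
    if "motif" in stages:
        m = config.get("motif", {})
        need("motif.targets", m.get("targets"))
        need("motif.background", m.get("background"))
        need("motif.pwm", m.get("pwm"))
    if len(namespaces) >= 2:
        try:
            check_chrom_namespaces(namespaces)
        except FormatError as exc:
            findings.append(Finding("error", str(exc)))
    return findings


def _meta_lines(meta: Mapping[str, Any]) -> str:
    return "".join(f"# {key}={value}\n" for key, value in meta.items())


def _write_table(df: pd.DataFrame, path: Path, meta: Mapping[str, Any]) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def run_full(
    config: Mapping[str, Any],
    base_dir: str | Path = ".",
    outdir: str | Path = "regdomain_out",
    seed: int | None = None,
    reproducible: bool = False,
) -> Path:
    """Execute the configured stages in order and write the report directory.

    Raises on any validation error before touching the output directory.
    """
    findings = validate_inputs(config, base_dir)
    errors = [f for f in findings if f.level == "error"]
    for f in findings:
        (log.error if f.level == "error" else log.warning)("%s", f.message)
    if errors:
        raise FormatError(f"{len(errors)} validation error(s); nothing was run")

    base = Path(base_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    meta: dict[str, Any] = {
        "tool": f"regdomain v{__version__}",
        "config_sha256": config_hash(config),
        "seed": seed if seed is not None else "none",
    }
    if not reproducible:
        meta["generated_utc"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    manifest: dict[str, Any] = {"meta": dict(meta), "stages": {}}

    peaks = None
    if config.get("peaks"):
        peaks = read_bed(_resolve(base, config["peaks"]))

    if "consensus" in stages:
        ccfg = config["consensus"]
        anchor = read_bed(_resolve(base, ccfg["anchor"]))
        others = [read_bed(_resolve(base, p)) for p in ccfg["against"]]
        result = consensus(anchor, others)
        write_bed(result, out / "consensus.bed")
        manifest["stages"]["consensus"] = {
            "anchor": ccfg["anchor"],
            "against": list(ccfg["against"]),
            "n_anchor": len(anchor),
            "n_consensus": len(result),
            "note": "counts are anchor-set intervals (anchored >=1 bp overlap with every comparison set)",
        }
        meta["consensus_anchor"] = ccfg["anchor"]
        if peaks is None:
            peaks = result

    if "venn3" in stages:
        vcfg = config["venn3"]
        labels = tuple(vcfg["sets"].keys())
        sets = [read_bed(_resolve(base, vcfg["sets"][l])) for l in labels]
        part = partition_three_way(*sets, labels=labels)
        venn_dir = out / "venn3"
        venn_dir.mkdir(exist_ok=True)
        emitted = {
            f"{labels[0]}_only": part.parts[labels[0]]["only"],
            f"{labels[1]}_only": part.parts[labels[1]]["only"],
            f"{labels[2]}_only": part.parts[labels[2]]["only"],
            f"{labels[0]}_and_{labels[1]}": part.parts[labels[0]]["and_second"],
            f"{labels[0]}_and_{labels[2]}": part.parts[labels[0]]["and_third"],
            f"{labels[1]}_and_{labels[2]}": part.parts[labels[1]]["and_third"],
            f"{labels[0]}_and_{labels[1]}_and_{labels[2]}": part.parts[labels[0]]["all_three"],
        }
        for fname, ivs in emitted.items():
            write_bed(ivs, venn_dir / f"{fname}.bed")
        _write_table(part.counts(), venn_dir / "counts.tsv",
                     {**meta, "note": "anchored partition; pairwise files use the first-named set's coordinates"})
        manifest["stages"]["venn3"] = {"labels": list(labels),
                                       "sizes": {l: len(s) for l, s in zip(labels, sets)}}

    genes = clusters = sizes = None
    if {"sweep", "tad_enrich"} & set(stages):
        genes = read_genes(_resolve(base, config["genes"]))
        sizes = read_chrom_sizes(_resolve(base, config["chrom_sizes"]))
        clusters = [read_cluster(_resolve(base, c), (g.gene_id for g in genes))
                    for c in config.get("clusters", [])]
        meta["gene_universe"] = len(genes)

    if "sweep" in stages:
        scfg = config.get("sweep", {}) or {}
        distances = scfg.get("distances", list(DEFAULT_DISTANCES))
        dom_map = None
        if scfg.get("domains"):
            dom_map = DomainMap(read_bed(_resolve(base, scfg["domains"]), kind="domains"))
        table = distance_sweep(peaks, genes, clusters, distances, sizes, domains=dom_map)
        _write_table(table, out / "sweep.tsv", meta)
        manifest["stages"]["sweep"] = {"distances": list(distances),
                                       "clusters": [c.name for c in clusters],
                                       "n_peaks": len(peaks)}

    if "tad_enrich" in stages:
        index = GeneIndex(genes)
        rows = []
        for dpath in config["tad_enrich"]["domains"]:
            dmap = DomainMap(read_bed(_resolve(base, dpath), kind="domains"))
            map_label = Path(dpath).stem
            for cluster in clusters:
                de = domain_enrichment(peaks, index.genes, cluster, dmap)
                rows.append(
                    {
                        "cluster": cluster.name,
                        "domain_map": map_label,
                        "N": de.result.N,
                        "K": de.result.K,
                        "n": de.result.n,
                        "k": de.result.k,
                        "pct_cluster": de.pct_cluster,
                        "pct_all": de.pct_all,
                        "p_upper": de.result.p_upper,
                        "neg_log10_p": de.result.neg_log10_p,
                    }
                )
        _write_table(
            pd.DataFrame(rows), out / "tad_enrichment.tsv",
            {**meta, "universe": "genes with a TSS inside any domain of the named map"},
        )
        manifest["stages"]["tad_enrich"] = {"domain_maps": list(config["tad_enrich"]["domains"])}

    if "motif" in stages:
        mcfg = config["motif"]
        pwm = PWM.from_jaspar(_resolve(base, mcfg["pwm"]))
        if mcfg.get("threshold") is not None:
            pwm.threshold = float(mcfg["threshold"])
        targets = RegionSeqSet.from_fasta(_resolve(base, mcfg["targets"]))
        background = RegionSeqSet.from_fasta(_resolve(base, mcfg["background"]))
        res = fold_enrichment(targets, background, pwm)
        _write_table(
            pd.DataFrame([vars(res)]), out / "motif.tsv",
            {**meta, "pwm_threshold": f"{pwm.threshold:.4f}"},
        )
        manifest["stages"]["motif"] = {"pwm": res.pwm_name,
                                       "n_target": res.n_target, "n_background": res.n_background}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
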