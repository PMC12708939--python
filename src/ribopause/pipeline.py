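"""Configuration-driven end-to-end runs: simulate → analyze → report.

Every run is deterministic given its seed and inputs: data files carry no
timestamps, iteration orders are fixed, and each stage writes tab-separated
tables.  A ``manifest.json`` records the seed, a hash of the effective
configuration and the SHA-256 checksum of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from . import expression, usage
from .footprints import (
    FootprintMatcher,
    alignments_frame,
    build_profile,
    periodicity,
    read_fastq,
)
from .occupancy import (
    DEFAULT_GROUPS,
    CodonSiteCounts,
    SiteSpec,
    count_by_codon_site,
    default_sites,
    differential_occupancy,
    group_counts,
)
from .simulate import SimConfig, simulate_counts, simulate_footprints, write_fastq
from .simulate import generate_transcriptome
from .transcripts import read_transcripts, write_transcripts

log = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or malformed input data (CLI exit code 3)."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # overrides of SimConfig fields
    "analysis": {
        "periodicity_threshold": 0.6,
        "replicate_sum": "normalize_then_sum",  # or "sum_then_normalize"
        "pseudocount": 1.0,
        "alpha": 0.05,
        "usage_group": "NAA",
        "usage_method": "rank",
        "wildtype": "wt",
        "mutant": "mut",
        "sites": None,  # optional {name: nt_offset}
        "groups": None,  # optional {name: [codons]}
    },
}


def load_config(path: str | Path | None, seed: int | None = None) -> dict:
    """Merge a YAML config file over the defaults; CLI seed wins."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file is not valid YAML: {exc}") from exc
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def sim_config(cfg: dict) -> SimConfig:
    known = {f.name for f in fields(SimConfig)}
    overrides = dict(cfg.get("simulate") or {})
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown simulate options: {sorted(unknown)}")
    if "cds_length_range" in overrides:
        overrides["cds_length_range"] = tuple(overrides["cds_length_range"])
    sc = SimConfig(seed=int(cfg.get("seed", 0)), **overrides)
    try:
        sc.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return sc


def _sites_from_config(cfg: dict) -> list[SiteSpec]:
    overrides = (cfg.get("analysis") or {}).get("sites")
    if not overrides:
        return default_sites()
    try:
        return [SiteSpec(name, int(off)) for name, off in overrides.items()]
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _groups_from_config(cfg: dict) -> dict[str, frozenset[str]]:
    overrides = (cfg.get("analysis") or {}).get("groups")
    if not overrides:
        return dict(DEFAULT_GROUPS)
    return {name: frozenset(codons) for name, codons in overrides.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: dict, files: list[Path]) -> dict:
    manifest = {
        "seed": cfg.get("seed", 0),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_simulate(cfg: dict, outdir: str | Path) -> dict:
    """Generate a full synthetic data set; returns the manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {outdir}: {exc}") from exc
    sc = sim_config(cfg)
    transcripts = generate_transcriptome(sc)
    files: list[Path] = []

    fasta, cds = outdir / "transcripts.fasta", outdir / "cds.tsv"
    write_transcripts(transcripts, fasta, cds)
    files += [fasta, cds]

    for cond in sorted(sc.dwell_multipliers):
        for rep in range(1, sc.n_replicates + 1):
            reads, truth = simulate_footprints(transcripts, sc, cond, rep)
            fq = outdir / f"reads_{cond}_{rep}.fastq"
            tt = outdir / f"footprint_truth_{cond}_{rep}.tsv"
            write_fastq(reads, fq)
            truth.to_csv(tt, sep="\t", index=False)
            files += [fq, tt]

    rna, ribo, te_truth = simulate_counts(transcripts, sc)
    for df, name in [(rna, "rna_counts.tsv"), (ribo, "ribo_counts.tsv")]:
        df.to_csv(outdir / name, sep="\t")
        files.append(outdir / name)
    te_truth.to_csv(outdir / "te_truth.tsv", sep="\t", index=False)
    files.append(outdir / "te_truth.tsv")
    return _write_manifest(outdir, cfg, files)


def _aggregate_counts(per_rep: list[CodonSiteCounts], mode: str) -> CodonSiteCounts:
    """Combine replicate-level codon-site tables for one condition."""
    total = sum(c.library_total for c in per_rep)
    base = per_rep[0]
    table = base.table[["codon", "site"]].copy()
    raw = sum(c.table["raw"].to_numpy() for c in per_rep)
    table["raw"] = raw
    if mode == "normalize_then_sum":
        table["normalized"] = sum(c.table["normalized"].to_numpy() for c in per_rep)
    elif mode == "sum_then_normalize":
        table["normalized"] = raw * (1e6 / total if total else 0.0)
    else:
        raise ConfigError(f"unknown replicate_sum mode {mode!r}")
    return CodonSiteCounts(base.condition, table, total, base.sites)


ANALYSIS_STAGES = ("footprints", "occupancy", "expression", "usage")


def run_analysis(
    cfg: dict,
    datadir: str | Path,
    outdir: str | Path,
    stages: tuple[str, ...] = ANALYSIS_STAGES,
) -> dict:
    """Run analysis stages on a (simulated or real) data directory."""
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ana = cfg["analysis"]
    files: list[Path] = []
    log_lines: list[str] = []

    fasta, cds = datadir / "transcripts.fasta", datadir / "cds.tsv"
    for p in (fasta, cds):
        if not p.exists():
            raise DataError(f"missing input file: {p}")
    transcripts = read_transcripts(fasta, cds, strict=False)
    log_lines.append(f"transcripts: {len(transcripts)}")

    need_footprints = {"footprints", "occupancy"} & set(stages)
    alignments_by_cond: dict[str, list] = {}
    totals_by_cond_rep: dict[str, list[int]] = {}
    if need_footprints:
        matcher = FootprintMatcher(transcripts)
        fastqs = sorted(datadir.glob("reads_*.fastq"))
        if not fastqs:
            raise DataError(f"no reads_*.fastq files in {datadir}")
        for fq in fastqs:
            cond, rep = fq.stem.split("_")[1], fq.stem.split("_")[2]
            sample = f"{cond}_{rep}"
            alns, counters = matcher.match(read_fastq(fq))
            log_lines.append(
                f"{sample}: accepted={counters['accepted']} "
                f"wrong_length={counters['wrong_length']} "
                f"no_match={counters['no_match']} "
                f"multi_match={counters['multi_match']}"
            )
            alignments_by_cond.setdefault(cond, []).append(alns)
            totals_by_cond_rep.setdefault(cond, []).append(len(alns))

            if "footprints" in stages:
                af = alignments_frame(alns)
                p = outdir / f"alignments_{sample}.tsv"
                af.to_csv(p, sep="\t", index=False)
                files.append(p)

                prof_rows, period_rows = [], []
                total = max(len(alns), 1)
                for t in transcripts:
                    prof = build_profile(alns, t, sample, total)
                    nz = prof.counts.nonzero()[0]
                    prof_rows += [
                        (t.transcript_id, int(i), int(prof.counts[i]),
                         float(prof.normalized[i]), sample)
                        for i in nz
                    ]
                    per = periodicity(prof, t, ana["periodicity_threshold"])
                    period_rows.append(
                        (t.transcript_id, sample, per.f0, per.f1, per.f2, per.passed)
                    )
                pd.DataFrame(
                    prof_rows,
                    columns=["transcript_id", "position", "count", "normalized", "sample"],
                ).to_csv(outdir / f"profile_{sample}.tsv", sep="\t", index=False)
                pd.DataFrame(
                    period_rows,
                    columns=["transcript_id", "sample", "f0", "f1", "f2", "passed"],
                ).to_csv(outdir / f"periodicity_{sample}.tsv", sep="\t", index=False)
                files += [outdir / f"profile_{sample}.tsv",
                          outdir / f"periodicity_{sample}.tsv"]

    if "occupancy" in stages:
        sites = _sites_from_config(cfg)
        groups = _groups_from_config(cfg)
        grouped = {}
        for cond, rep_alns in sorted(alignments_by_cond.items()):
            per_rep = [
                count_by_codon_site(a, transcripts, sites, n, cond)
                for a, n in zip(rep_alns, totals_by_cond_rep[cond])
            ]
            agg = _aggregate_counts(per_rep, ana["replicate_sum"])
            agg.table.to_csv(outdir / f"codon_site_{cond}.tsv", sep="\t", index=False)
            files.append(outdir / f"codon_site_{cond}.tsv")
            grouped[cond] = group_counts(agg, groups)
            grouped[cond].table.to_csv(
                outdir / f"grouped_{cond}.tsv", sep="\t", index=False
            )
            files.append(outdir / f"grouped_{cond}.tsv")
        wt, mut = ana["wildtype"], ana["mutant"]
        if wt in grouped and mut in grouped:
            diff = differential_occupancy(grouped[mut], grouped[wt])
            diff.table.to_csv(outdir / "differential.tsv", sep="\t", index=False)
            files.append(outdir / "differential.tsv")
            log_lines.append(f"differential: {mut} - {wt}")

    records = None
    if "expression" in stages:
        rna_p, ribo_p = datadir / "rna_counts.tsv", datadir / "ribo_counts.tsv"
        for p in (rna_p, ribo_p):
            if not p.exists():
                raise DataError(f"missing input file: {p}")
        model = expression.TranslationalEfficiency.from_tsv(
            rna_p, ribo_p, wildtype=ana["wildtype"], mutant=ana["mutant"]
        )
        res = model.fit(
            pseudocount=ana["pseudocount"],
            alpha=ana["alpha"],
            seed=int(cfg.get("seed", 0)),
        )
        records = res.records
        records.to_csv(outdir / "expression_records.tsv", sep="\t")
        res.ma_table().to_csv(outdir / "ma_table.tsv", sep="\t", index=False)
        files += [outdir / "expression_records.tsv", outdir / "ma_table.tsv"]
        log_lines.append(
            f"expression: {len(records)} genes, "
            f"{int(records['tested'].sum())} tested, "
            f"{int(records['significant'].sum())} significant"
        )

    if "usage" in stages:
        if records is None:
            rec_p = outdir / "expression_records.tsv"
            if not rec_p.exists():
                raise DataError("usage stage needs expression records; run expression first")
            records = pd.read_csv(rec_p, sep="\t", index_col=0)
        groups = _groups_from_config(cfg)
        table = usage.codon_usage_table(transcripts, groups)
        table.to_csv(outdir / "codon_usage.tsv", sep="\t")
        files.append(outdir / "codon_usage.tsv")
        coef, pval, n = usage.usage_te_correlation(
            table, records, group=ana["usage_group"], method=ana["usage_method"]
        )
        pd.DataFrame(
            [
                {
                    "group": ana["usage_group"],
                    "method": ana["usage_method"],
                    "coefficient": coef,
                    "pvalue": pval,
                    "n": n,
                }
            ]
        ).to_csv(outdir / "usage_correlation.tsv", sep="\t", index=False)
        files.append(outdir / "usage_correlation.tsv")
        log_lines.append(f"usage correlation ({ana['usage_group']}): {coef}")

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return _write_manifest(outdir, cfg, files)
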