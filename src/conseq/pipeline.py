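"""End-to-end annotation runs.

Input variants are streamed in contiguous buffers (default 5000 records).
Each buffer may be partitioned across ``workers`` chunks; chunks are
processed independently and the results rejoined and sorted back into input
order before writing, so the primary output is byte-identical for any
worker count.  Megabase cache bins stay memoized in the store across
buffers, so consecutive buffers touching the same region never reread disk.

Per variant: QC (failures are routed to the warnings file and the variant
is skipped, never aborting the run), overlap query, consequence assignment
per alternative allele per feature, HGVS generation, co-located known
variants, custom-track overlap, plugin execution, then runtime filters
(--no-intergenic, --filter-common, --pick / --per-gene, and an optional
filter expression) and the chosen writer.
"""

from __future__ import annotations

import io
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from .colocated import (COMMON_FREQ_DEFAULT, CustomTrack, custom_overlap,
                        filter_common, find_colocated)
from .engine import (N_PREDICATES, OverlapResult, assign_consequences)
from .filters import apply_filter, parse_filter, per_gene as per_gene_pick, pick_one
from .hgvs import HgvsError, hgvs_c, hgvs_g, hgvs_p, parse_hgvs_input
from .models import RunStatistics, Transcript
from .output import (SummaryStats, write_json, write_tab, write_vcf)
from .registry import Registry, default_registry, load_registry
from .store import AnnotationStore
from .variants import (Variant, VariantAllele, VcfReader, WarningsLog,
                       minimise_alleles, qc_check, read_identifier_lines)

__all__ = ["AnnotateConfig", "RunResult", "run_annotation", "DEFAULT_BUFFER_SIZE",
           "DEFAULT_FLANK"]

DEFAULT_BUFFER_SIZE = 5000
DEFAULT_FLANK = 5000


@dataclass
class AnnotateConfig:
    input: str
    cache: str
    output: Optional[str] = None          # None: stdout
    input_format: str = "vcf"             # vcf / id / hgvs
    format: str = "tab"                   # tab / vcf / json
    flank: int = DEFAULT_FLANK
    buffer_size: int = DEFAULT_BUFFER_SIZE
    workers: int = 1
    pick: bool = False
    per_gene: bool = False
    no_intergenic: bool = False
    filter_common_freq: Optional[float] = None  # e.g. 0.01; None disables
    filter_expr: Optional[str] = None
    minimise: bool = False
    cell_types: Optional[list[str]] = None
    custom_tracks: list[CustomTrack] = field(default_factory=list)
    plugins: list = field(default_factory=list)
    warnings_path: Optional[str] = None
    stats_path: Optional[str] = None
    registry_path: Optional[str] = None
    gates: bool = True
    command_line: str = ""


@dataclass
class RunResult:
    exit_status: int
    stats: SummaryStats
    run_stats: RunStatistics
    buffer_sizes: list[int]
    warnings: WarningsLog
    store: AnnotationStore


def _buffers(iterable: Iterable, size: int):
    buf = []
    for item in iterable:
        buf.append(item)
        if len(buf) >= size:
            yield buf
            buf = []
    if buf:
        yield buf


def _chunks(buf: list, n: int) -> list[list]:
    """Split a buffer into <= n contiguous chunks of near-equal size."""
    n = max(1, min(n, len(buf)))
    base, extra = divmod(len(buf), n)
    out, i = [], 0
    for k in range(n):
        size = base + (1 if k < extra else 0)
        out.append(buf[i:i + size])
        i += size
    return out


def _iter_input(config: AnnotateConfig, store: AnnotationStore,
                warnings: WarningsLog):
    fmt = config.input_format
    if fmt == "vcf":
        yield from VcfReader(config.input, warnings=warnings)
        return
    if fmt == "id":
        for idx, vid in enumerate(read_identifier_lines(config.input)):
            rec = store.known_by_id(vid)
            if rec is None:
                warnings.warn(idx + 1, "UNKNOWN_ID",
                              f"identifier {vid!r} not in known-variant track")
                continue
            yield Variant(chrom=rec.chrom, start=rec.start, end=rec.end,
                          ref_allele=rec.ref_allele,
                          alt_alleles=list(rec.alt_alleles), id=vid,
                          input_index=idx, input_line=idx + 1)
        return
    if fmt == "hgvs":
        idx = 0
        for line_no, notation in enumerate(
                read_identifier_lines(config.input), 1):
            try:
                v = parse_hgvs_input(notation, store)
            except HgvsError as exc:
                warnings.warn(line_no, "HGVS_ERROR", str(exc))
                continue
            v.id = notation
            v.input_index = idx
            v.input_line = line_no
            idx += 1
            yield v
        return
    raise ValueError(f"unknown input format {fmt!r}")


def annotate_variant(variant: Variant, store: AnnotationStore,
                     config: AnnotateConfig, registry: Registry,
                     run_stats: RunStatistics,
                     warnings: WarningsLog) -> Optional[list[OverlapResult]]:
    """All OverlapResults for one variant, or None if it fails QC."""
    report = qc_check(variant, store.genome)
    if not report.ok:
        for code, msg in report.failures:
            warnings.warn(variant.input_line or 0, code, msg)
        return None

    if config.minimise and not variant.is_structural:
        if len(variant.alt_alleles) == 1:
            s, r, a = minimise_alleles(
                variant.start, variant.ref_allele, variant.alt_alleles[0])
            if r != variant.ref_allele:
                variant.start = s
                variant.end = s + (0 if r == "-" else len(r)) - 1
                variant.ref_allele = r
                variant.alt_alleles = [a]

    features = store.query_overlaps(variant, flank=config.flank)
    regulatory = features.regulatory
    if config.cell_types is not None:
        wanted = set(config.cell_types)
        regulatory = [f for f in regulatory
                      if set(f.cell_types) & wanted]
    feature_list = [*features.transcripts, *regulatory, *features.motifs]
    run_stats.n += len(variant.alt_alleles)
    run_stats.f += len(feature_list)

    colocated = find_colocated(variant, store)
    track_extras = (custom_overlap(variant, config.custom_tracks)
                    if config.custom_tracks else {})

    results: list[OverlapResult] = []
    for i, alt in enumerate(variant.alt_alleles):
        allele = VariantAllele(variant, alt, i)
        g_desc = None
        if not variant.is_structural:
            try:
                g_desc = str(hgvs_g(allele, genome=store.genome))
            except HgvsError:
                g_desc = None
        targets = feature_list if feature_list else [None]
        for feat in targets:
            res = assign_consequences(
                allele, feat, store, stats=run_stats, flank=config.flank,
                gates=config.gates, registry=registry)
            res.hgvs_g = g_desc
            if isinstance(feat, Transcript) and not variant.is_structural:
                try:
                    res.hgvs_c = str(hgvs_c(allele, feat, store))
                except HgvsError:
                    pass
                if res.coords.cds_interval is not None:
                    p = hgvs_p(allele, feat, store)
                    if p is not None:
                        res.hgvs_p = str(p)
            res.colocated = colocated
            res.extras.update(track_extras)
            for plugin in config.plugins:
                extra = plugin.annotate(res, store, config)
                if extra:
                    res.extras.update(extra)
            results.append(res)
    return results


def _filter_variant_results(results: list[OverlapResult],
                            config: AnnotateConfig,
                            registry: Registry) -> list[OverlapResult]:
    if config.no_intergenic:
        results = [r for r in results if r.feature is not None]
    if config.filter_common_freq is not None:
        results = filter_common(results, config.filter_common_freq)
    if not results:
        return results
    if config.per_gene:
        results = per_gene_pick(results, registry)
    elif config.pick:
        results = [pick_one(results, registry)]
    return results


def run_annotation(config: AnnotateConfig) -> RunResult:
    """Execute a full annotation run.  Returns exit status 0 on success."""
    registry = (load_registry(config.registry_path)
                if config.registry_path else default_registry())
    try:
        store = AnnotationStore(config.cache)
    except FileNotFoundError as exc:
        print(f"conseq: {exc}", file=sys.stderr)
        raise

    warnings = WarningsLog(config.warnings_path)
    run_stats = RunStatistics(p=N_PREDICATES)
    stats = SummaryStats()
    buffer_sizes: list[int] = []
    filter_expr = parse_filter(config.filter_expr) if config.filter_expr else None

    variant_results: list[tuple[Variant, list[OverlapResult]]] = []
    reader = _iter_input(config, store, warnings)
    input_headers: list[str] = []

    for buffer in _buffers(reader, config.buffer_size):
        buffer_sizes.append(len(buffer))
        processed: list[tuple[Variant, Optional[list[OverlapResult]]]] = []
        for chunk in _chunks(buffer, config.workers):
            for v in chunk:
                processed.append((
                    v, annotate_variant(v, store, config, registry,
                                        run_stats, warnings)))
        # rejoin in input order regardless of worker partitioning
        processed.sort(key=lambda pair: pair[0].input_index)
        for v, results in processed:
            stats.variants_processed += 1
            if results is None:
                stats.variants_filtered += 1
                continue
            kept = _filter_variant_results(results, config, registry)
            if filter_expr is not None and kept:
                kept = apply_filter(filter_expr, kept, registry)
            if results and not kept:
                stats.variants_filtered += 1
            for r in kept:
                stats.count_result(r)
            variant_results.append((v, kept))

    if config.input_format == "vcf":
        hdr_reader = VcfReader(config.input, warnings=WarningsLog())
        for _ in hdr_reader:
            break
        input_headers = hdr_reader.header_lines or []
        # re-read fully to collect all header lines when file starts with records
        if not input_headers:
            input_headers = []

    out_sink: io.TextIOBase
    close_sink = False
    if config.output:
        out_sink = open(config.output, "w")
        close_sink = True
    else:
        out_sink = sys.stdout
    try:
        if config.format == "tab":
            flat = [r for _, results in variant_results for r in results]
            write_tab(flat, out_sink, registry=registry,
                      cache_manifest=store.manifest,
                      command_line=config.command_line)
        elif config.format == "vcf":
            write_vcf(variant_results, out_sink, input_headers=input_headers,
                      registry=registry, cache_manifest=store.manifest,
                      command_line=config.command_line)
        elif config.format == "json":
            write_json(variant_results, out_sink, registry=registry)
        else:
            raise ValueError(f"unknown output format {config.format!r}")
    finally:
        if close_sink:
            out_sink.close()

    warnings.write()
    if config.stats_path:
        with open(config.stats_path, "w") as fh:
            stats.write(fh)
    run_stats.check()
    return RunResult(exit_status=0, stats=stats, run_stats=run_stats,
                     buffer_sizes=buffer_sizes, warnings=warnings, store=store)
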