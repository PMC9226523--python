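"""End-to-end sample processing: FASTQ -> filter -> align -> classify -> summary."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

from .amplicon import AmpliconReference
from .align import ScoringScheme, call_variants, is_unalignable
from .classify import ClassifiedRead, RepairClass, classify_read, classification_table
from .reads import FilterReport, SequencingRead, filter_reads, read_fastq
from .summarize import RepairSummary, summarize_sample


def classify_reads(
    reads: Iterable[SequencingRead],
    ref: AmpliconReference,
    scoring: ScoringScheme = ScoringScheme(),
    **classify_kwargs,
) -> list[ClassifiedRead]:
    """Align and classify oriented, anchor-passing reads."""
    out: list[ClassifiedRead] = []
    for read in reads:
        variants, aln = call_variants(read.bases, ref, scoring)
        if is_unalignable(aln):
            out.append(ClassifiedRead(read_id=read.id, repair_class=RepairClass.UNALIGNABLE))
            continue
        out.append(classify_read(variants, ref, read_id=read.id, **classify_kwargs))
    return out


def run_sample(
    fastq_path,
    ref: AmpliconReference,
    sample_id: Optional[str] = None,
    scoring: ScoringScheme = ScoringScheme(),
    max_mismatch: int = 2,
) -> tuple[FilterReport, list[ClassifiedRead], RepairSummary]:
    """Process one FASTQ sample end to end."""
    sample_id = sample_id or Path(fastq_path).stem
    kept, report = filter_reads(read_fastq(fastq_path), ref, max_mismatch=max_mismatch)
    classified = classify_reads(kept, ref, scoring)
    summary = summarize_sample(classified, sample_id=sample_id)
    return report, classified, summary


def write_outputs(
    outdir,
    report: FilterReport,
    classified: Sequence[ClassifiedRead],
    summary: RepairSummary,
) -> None:
    """Emit the per-sample artefacts: filter JSON, per-read TSV, summary JSON,
    tornado TSV."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "filter_report.json").write_text(report.to_json())
    classification_table(classified).to_csv(outdir / "classified_reads.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(summary.to_json())
    pd.DataFrame(
        [
            {
                "rank": t.rank,
                "class": t.repair_class.value,
                "del_start": t.del_start,
                "del_end": t.del_end,
                "ins_len": t.ins_len,
                "event_size": t.event_size,
            }
            for t in summary.tornado
        ]
    ).to_csv(outdir / "tornado.tsv", sep="\t", index=False)
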