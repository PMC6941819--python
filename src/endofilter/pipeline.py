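"""End-to-end orchestration: features -> stage-1 recurrence filter ->
stage-2 classifier -> annotated output and before/after reports.

Every input variant ends in exactly one terminal state: removed by the
recurrence filter, removed by the model, or retained; whitelist-rescued calls
go through the model like everything else, so the accounting always closes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import LABEL_ARTIFACT, LogisticNoiseClassifier, bias_feature
from .cohort import RecurrenceTable, StageOneDecision, build_recurrence, stage_one_filter
from .evidence import (
    UncallableVariantError,
    collect_evidence,
    positional_bias,
    soft_clip_ratio,
)
from .io import VariantCall, fetch_reads_at
from .palindrome import DEFAULT_MAX_ARM, scp_for_variant
from .signatures import MutationSpectrum, SignatureMatrix, refit_exposures

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "n_alt",
    "n_ref",
    "ks_p",
    "ks_D",
    "soft_clip_ratio",
    "x_bias",
    "x_clip",
    "scp_len",
    "callable",
]


@dataclass
class FilterReport:
    """Per-run bookkeeping of the two filtering stages."""

    n_input: int = 0
    n_removed_recurrent: int = 0
    n_rescued_whitelist: int = 0
    n_removed_model: int = 0
    n_retained: int = 0
    per_sample: pd.DataFrame | None = None

    @property
    def closes(self) -> bool:
        return self.n_input == self.n_removed_recurrent + self.n_removed_model + self.n_retained

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "removed_recurrent": self.n_removed_recurrent,
            "rescued_whitelist": self.n_rescued_whitelist,
            "removed_model": self.n_removed_model,
            "retained": self.n_retained,
        }


def extract_features(
    calls: Sequence[VariantCall],
    bam: str | Path,
    fasta: str | Path,
    *,
    transform: str = "distance_to_nearest_end",
    min_clip: int = 1,
    max_arm: int = DEFAULT_MAX_ARM,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Per-variant feature table: read counts, KS positional bias, soft-clip
    ratio, SCP length, and the classifier inputs (x_bias, x_clip).

    Variants with no alt-supporting reads are flagged ``callable=False`` with
    NaN features; they cannot be assessed and the filter retains them.
    """
    rows = []
    for v in calls:
        row = {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
        }
        reads = fetch_reads_at(bam, v.chrom, v.pos, min_mapq=min_mapq)
        try:
            ev = collect_evidence(reads, v, min_clip=min_clip)
            bias = positional_bias(ev, transform=transform)
            clip = soft_clip_ratio(ev)
            row.update(
                n_alt=ev.n_alt,
                n_ref=ev.n_ref,
                ks_p=bias.ks_p,
                ks_D=bias.ks_D,
                soft_clip_ratio=clip,
                x_bias=float(bias_feature(bias.ks_p)),
                x_clip=clip,
                callable=True,
            )
        except UncallableVariantError:
            row.update(
                n_alt=0,
                n_ref=len(reads),
                ks_p=np.nan,
                ks_D=np.nan,
                soft_clip_ratio=np.nan,
                x_bias=np.nan,
                x_clip=np.nan,
                callable=False,
            )
        row["scp_len"] = scp_for_variant(v, fasta, max_arm=max_arm).scp_len
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def run_filter(
    calls: Sequence[VariantCall],
    bam: str | Path,
    fasta: str | Path,
    cohort_tables: Sequence[Sequence[VariantCall]],
    model: LogisticNoiseClassifier,
    whitelist: frozenset = frozenset(),
    *,
    recurrence_min: int = 2,
    leave_one_out: bool = True,
    recurrence: RecurrenceTable | None = None,
    features: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply both filter stages to one sample's calls.

    Stage 1 removes cohort-recurrent calls unless whitelisted; stage 2 runs
    the logistic model on the survivors (including whitelist rescues). Returns
    the annotated per-variant table and a closing :class:`FilterReport`.
    Precomputed ``recurrence``/``features`` tables are reused when given.
    """
    report = FilterReport(n_input=len(calls))
    if not calls:
        return pd.DataFrame(columns=FEATURE_COLUMNS + ["recurrence_count", "whitelisted", "stage1", "p_noise", "status"]), report

    table = recurrence if recurrence is not None else build_recurrence(cohort_tables)
    decisions = stage_one_filter(
        calls, table, whitelist, recurrence_min=recurrence_min, leave_one_out=leave_one_out
    )
    survivors = [d.variant for d in decisions if not d.removed]
    report.n_removed_recurrent = sum(d.removed for d in decisions)
    report.n_rescued_whitelist = sum(d.reason == "rescued_whitelist" for d in decisions)
    logger.info(
        "stage 1: %d input, %d removed recurrent, %d rescued by whitelist",
        report.n_input,
        report.n_removed_recurrent,
        report.n_rescued_whitelist,
    )

    if features is None:
        features = extract_features(survivors, bam, fasta)
    feats = features.set_index(["sample_id", "chrom", "pos", "ref", "alt"])

    rows = []
    for d in decisions:
        v = d.variant
        row = {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "recurrence_count": d.recurrence_count,
            "whitelisted": d.whitelisted,
            "stage1": d.reason,
        }
        if d.removed:
            row.update(p_noise=np.nan, status="removed_recurrent")
        else:
            f = feats.loc[(v.sample_id, v.chrom, v.pos, v.ref, v.alt)]
            if isinstance(f, pd.DataFrame):
                f = f.iloc[0]
            row.update(f.to_dict())
            if f["callable"]:
                p = float(
                    model.predict_proba(np.array([[f["x_bias"], f["x_clip"]]]))[0, LABEL_ARTIFACT]
                )
                row["p_noise"] = p
                row["status"] = "removed_model" if p >= model.threshold_ else "retained"
            else:
                row["p_noise"] = np.nan
                row["status"] = "retained"
        rows.append(row)
        logger.debug("%s:%s %s>%s -> %s", v.chrom, v.pos, v.ref, v.alt, row["status"])

    annotated = pd.DataFrame(rows)
    report.n_removed_model = int((annotated["status"] == "removed_model").sum())
    report.n_retained = int((annotated["status"] == "retained").sum())
    assert report.closes, "filter accounting must close"
    logger.info(
        "stage 2: %d removed by model, %d retained", report.n_removed_model, report.n_retained
    )
    return annotated, report


def annotated_to_calls(annotated: pd.DataFrame, statuses: Iterable[str]) -> list[VariantCall]:
    wanted = set(statuses)
    return [
        VariantCall(r.chrom, int(r.pos), r.ref, r.alt, r.sample_id)
        for r in annotated.itertuples()
        if r.status in wanted
    ]


def write_filtered_vcf(annotated: pd.DataFrame, path: str | Path, hard_filter: bool = False) -> None:
    """Minimal VCF 4.2 with FILTER tags (recurrent_artifact / model_noise).

    With ``hard_filter`` only retained records are written (all PASS).
    """
    tag = {"retained": "PASS", "removed_recurrent": "recurrent_artifact", "removed_model": "model_noise"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=recurrent_artifact,Description="Recurrent across pooled cohort, not whitelisted">\n')
        fh.write('##FILTER=<ID=model_noise,Description="Classified as fragmentation noise by logistic model">\n')
        fh.write('##INFO=<ID=KS_P,Number=1,Type=Float,Description="Positional-bias KS p-value">\n')
        fh.write('##INFO=<ID=CLIP,Number=1,Type=Float,Description="Soft-clipped alt read ratio">\n')
        fh.write('##INFO=<ID=SCP,Number=1,Type=Integer,Description="SNV-centered palindrome length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in annotated.sort_values(["chrom", "pos"]).itertuples():
            if hard_filter and r.status != "retained":
                continue
            info = []
            ks_p = getattr(r, "ks_p", np.nan)
            if pd.notna(ks_p):
                info.append(f"KS_P={ks_p:.3g}")
            clip = getattr(r, "soft_clip_ratio", np.nan)
            if pd.notna(clip):
                info.append(f"CLIP={clip:.3g}")
            scp = getattr(r, "scp_len", np.nan)
            if pd.notna(scp):
                info.append(f"SCP={int(scp)}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{tag[r.status]}\t"
                + (";".join(info) or ".")
                + "\n"
            )


def run_report(
    annotated: pd.DataFrame,
    fasta: str | Path,
    matrix: SignatureMatrix | None = None,
    *,
    max_arm: int = DEFAULT_MAX_ARM,
) -> dict:
    """Before/after summary tables from an annotated filter output.

    Returns per-sample counts, aggregate SCP spectra before and after
    filtering, and (when a signature matrix is supplied) per-sample exposure
    tables before and after.
    """
    from .palindrome import scp_spectrum

    before = annotated_to_calls(annotated, {"retained", "removed_recurrent", "removed_model"})
    after = annotated_to_calls(annotated, {"retained"})

    counts = (
        annotated.groupby(["sample_id", "status"]).size().unstack(fill_value=0).reset_index()
    )
    clip_bins = np.arange(0.0, 1.05, 0.05)

    def clip_hist(mask):
        vals = annotated.loc[mask, "soft_clip_ratio"].dropna() if "soft_clip_ratio" in annotated else []
        counts_, _ = np.histogram(vals, bins=clip_bins)
        return counts_

    out: dict = {
        "counts": counts,
        "scp_before": scp_spectrum(before, fasta, max_arm=max_arm),
        "scp_after": scp_spectrum(after, fasta, max_arm=max_arm),
        "clip_hist_bins": clip_bins,
        "clip_hist_before": clip_hist(annotated.status.notna()),
        "clip_hist_after": clip_hist(annotated.status == "retained"),
    }
    if matrix is not None:
        exposures = {}
        for phase, calls in (("before", before), ("after", after)):
            rows = {}
            for sid in sorted({c.sample_id for c in calls}):
                spec, _ = MutationSpectrum.from_variants(
                    [c for c in calls if c.sample_id == sid], fasta
                )
                if spec.total_snvs > 0:
                    rows[sid] = refit_exposures(spec, matrix).weights
            exposures[phase] = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.names)
        out["exposures_before"] = exposures["before"]
        out["exposures_after"] = exposures["after"]
    return out


def train_classifier(
    features: pd.DataFrame, labels: Mapping[tuple, str] | pd.Series
) -> LogisticNoiseClassifier:
    """Fit the stage-2 model from a feature table and artifact/genuine labels.

    ``labels`` maps (sample_id, chrom, pos, ref, alt) to "artifact"/"genuine";
    only callable variants enter the fit.
    """
    feats = features[features["callable"]].copy()
    if isinstance(labels, pd.Series):
        lab = labels
    else:
        lab = pd.Series(
            [
                labels[(r.sample_id, r.chrom, r.pos, r.ref, r.alt)]
                for r in feats.itertuples()
            ],
            index=feats.index,
        )
    y = (lab == "artifact").astype(int).to_numpy()
    X = feats[["x_bias", "x_clip"]].to_numpy(dtype=float)
    return LogisticNoiseClassifier().fit(X, y)
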