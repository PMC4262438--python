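"""Corpus-level plumbing: read article files, run the checker, aggregate.

Drives scan -> validate -> recompute -> classify over a collection of article
files (plain text or HTML), joins optional article metadata (journal labels,
co-piloting counts), and produces two tables: one row per extracted result
and one row per article.  Unreadable files are recorded and skipped; the run
continues.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .consistency import classify
from .grammar import Validation, scan_text, validate_report
from .recompute import p_interval_from_stat

__all__ = ["check_corpus", "check_texts", "code_copiloting", "read_article",
           "RESULT_COLUMNS", "ARTICLE_COLUMNS"]

logger = logging.getLogger("reportcheck")

RESULT_COLUMNS = [
    "article_id", "study_id", "family", "df1", "df2", "n",
    "stat_comp", "stat", "stat_dec", "p_comp", "p", "p_dec",
    "one_tailed", "sig_wording", "span_start", "span_end", "raw",
    "computed_p", "p_lo", "p_hi", "consistent", "error", "gross_error",
    "one_tailed_applied", "reason",
]

ARTICLE_COLUMNS = [
    "article_id", "journal", "n_reports", "n_errors", "n_gross",
    "any_error", "any_gross", "first_study_only",
]

_HTML_SUFFIXES = {".html", ".htm", ".xhtml"}


def read_article(path) -> str:
    """Read one article file as text; HTML files are tag-stripped first."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8", errors="replace")
    if path.suffix.lower() in _HTML_SUFFIXES:
        from lxml import html as lxml_html

        tree = lxml_html.fromstring(raw)
        raw = tree.text_content()
    return raw


def check_texts(texts: Mapping[str, str], *, metadata: Optional[pd.DataFrame] = None,
                alpha: float = 0.05, sidedness_window: int = 200,
                first_study_only: bool = False) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the checker over in-memory documents keyed by article id.

    Returns ``(results, articles)``: the per-result verdict table and the
    per-article aggregation.  Reports that fail validation (power-of-ten
    notation, p > 1, statistics outside the null support) are logged and
    excluded, mirroring their exclusion from prevalence analyses.
    """
    meta = _prepare_metadata(metadata)
    rows = []
    per_article = []
    for article_id, text in texts.items():
        scanned = scan_text(text, article_id, sidedness_window=sidedness_window)
        for cand in scanned.skipped:
            logger.info("skipped candidate in %s at %d (%s): %r",
                        article_id, cand.offset, cand.reason, cand.raw)
        n_valid = 0
        for report in scanned:
            verdict = validate_report(report)
            if verdict is not Validation.VALID:
                logger.info("excluded result in %s at %d (%s): %r",
                            article_id, report.span_start, verdict.value, report.raw)
                continue
            interval = p_interval_from_stat(report)
            result = classify(report, interval, alpha=alpha)
            rows.append(result.to_row())
            n_valid += 1
        per_article.append({"article_id": article_id, "n_scanned": n_valid})

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    articles = _aggregate_articles(results, [p["article_id"] for p in per_article],
                                   meta, first_study_only)
    return results, articles


def check_corpus(paths: Sequence, *, metadata: Optional[pd.DataFrame] = None,
                 alpha: float = 0.05, sidedness_window: int = 200,
                 first_study_only: bool = False) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the checker over article files; see :func:`check_texts`.

    The article id is the file stem unless the metadata table overrides it.
    A file that cannot be read is logged as a per-file error and the run
    continues with the remaining files.
    """
    texts = {}
    for path in paths:
        path = Path(path)
        article_id = path.stem
        try:
            texts[article_id] = read_article(path)
        except OSError as exc:
            logger.error("unreadable file %s: %s", path, exc)
    return check_texts(texts, metadata=metadata, alpha=alpha,
                       sidedness_window=sidedness_window,
                       first_study_only=first_study_only)


def code_copiloting(involvement_count: int) -> int:
    """Binary co-piloting code: 1 when two or more persons were involved."""
    if involvement_count < 1:
        raise ValueError("involvement count must be at least 1")
    return 1 if involvement_count >= 2 else 0


def _prepare_metadata(metadata: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
    if metadata is None:
        return None
    if "article_id" not in metadata.columns:
        raise ValueError("metadata must have an article_id column")
    if metadata["article_id"].duplicated().any():
        dupes = metadata.loc[metadata["article_id"].duplicated(), "article_id"].tolist()
        raise ValueError(f"duplicate article_id in metadata: {dupes}")
    return metadata.set_index("article_id")


def _aggregate_articles(results: pd.DataFrame, article_ids: Iterable[str],
                        meta: Optional[pd.DataFrame],
                        first_study_only: bool) -> pd.DataFrame:
    subset = results
    applied_restriction = False
    if first_study_only and "study_id" in results.columns:
        known = results["study_id"].dropna()
        if not known.empty:
            first = {aid: g.min() for aid, g in known.groupby(results["article_id"])}
            mask = results.apply(
                lambda r: r["study_id"] is not None
                and r["study_id"] == first.get(r["article_id"]), axis=1)
            subset = results[mask]
            applied_restriction = True

    rows = []
    grouped = subset.groupby("article_id") if len(subset) else None
    for article_id in article_ids:
        if grouped is not None and article_id in grouped.groups:
            g = grouped.get_group(article_id)
            n_reports = len(g)
            n_errors = int(g["error"].sum())
            n_gross = int(g["gross_error"].sum())
        else:
            n_reports = n_errors = n_gross = 0
        journal = None
        if meta is not None and article_id in meta.index and "journal" in meta.columns:
            journal = meta.loc[article_id, "journal"]
        rows.append({
            "article_id": article_id,
            "journal": journal,
            "n_reports": n_reports,
            "n_errors": n_errors,
            "n_gross": n_gross,
            "any_error": n_errors > 0,
            "any_gross": n_gross > 0,
            "first_study_only": applied_restriction,
        })
    articles = pd.DataFrame(rows, columns=ARTICLE_COLUMNS)
    if meta is not None:
        extra = [c for c in meta.columns if c.startswith("copilot_")]
        if extra:
            articles = articles.merge(meta[extra], left_on="article_id",
                                      right_index=True, how="left")
    return articles
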