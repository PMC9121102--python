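"""Degradome (PARE) 5'-tag density profiles and cleavage-site categories.

Each PARE tag marks the 5' end of an uncapped mRNA fragment; a depth peak at
the position opposite miRNA positions 10-11 of a predicted site evidences
miRNA-guided cleavage. Sites are ranked into five confidence categories by
comparing the tag depth d at the predicted position against the transcript's
depth maximum M and median (both over positions with at least one read):

* 0: d equals a unique maximum,
* 1: d equals a tied maximum,
* 2: median < d < M,
* 3: 1 < d <= median,
* 4: d == 1.

Only categories 0 and 1 are kept as confirmation by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .seqio import read_fasta

logger = logging.getLogger(__name__)

__all__ = ["build_density", "classify_category", "confirm_pairs", "load_tags"]


def load_tags(paths) -> list[str]:
    """Read PARE tag FASTA files into a flat list of tag sequences."""
    tags: list[str] = []
    for p in paths:
        tags.extend(read_fasta(p).values())
    return tags


def build_density(tags: list[str], transcripts: dict[str, str],
                  min_tag_len: int = 15) -> dict[str, np.ndarray]:
    """Per-transcript vector of 5'-end counts per position (0-based).

    Tags align exact-match; a tag matching several transcripts increments
    each of them (density-file semantics). Transcripts with no tags are
    omitted. The profile of each covered transcript sums to its mapped tag
    count.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    k = min_tag_len
    for tid, seq in transcripts.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((tid, i))
    profiles: dict[str, np.ndarray] = {}
    for tag in tags:
        tag = tag.upper()
        if len(tag) < k:
            continue
        for tid, i in index.get(tag[:k], ()):
            if transcripts[tid][i : i + len(tag)].upper() == tag:
                prof = profiles.get(tid)
                if prof is None:
                    prof = profiles[tid] = np.zeros(len(transcripts[tid]), dtype=np.int64)
                prof[i] += 1
    return profiles


def classify_category(profile: np.ndarray, position: int) -> int:
    """Category 0-4 of the depth at ``position`` (see module docstring)."""
    d = int(profile[position])
    if d < 1:
        raise ValueError("no degradome signal at the queried position")
    covered = profile[profile >= 1]
    M = int(covered.max())
    med = float(np.median(covered))
    if d == M:
        return 0 if (covered == M).sum() == 1 else 1
    if d == 1:
        return 4
    if d <= med:
        return 3
    return 2


def confirm_pairs(
    interactions: pd.DataFrame,
    profiles: dict[str, np.ndarray],
    keep: frozenset[int] | set[int] = frozenset({0, 1}),
    cut_offset: int = 10,
) -> pd.DataFrame:
    """Classify the predicted cleavage position of each interaction.

    The expected cleavage position is the transcript nucleotide paired to
    miRNA position ``cut_offset`` (1-based from the miRNA 5' end), i.e.
    ``site_end - cut_offset``. Returns rows (mirna_id, transcript_id,
    position, depth, category, confirmed) for interactions with signal;
    ``confirmed`` marks categories in ``keep``.
    """
    rows = []
    for _, r in interactions.iterrows():
        tid = r["transcript_id"]
        prof = profiles.get(tid)
        if prof is None:
            continue
        pos = int(r["site_end"]) - cut_offset
        if pos < 0 or pos >= len(prof):
            logger.warning(
                "cleavage position %d outside transcript %s; interaction skipped",
                pos, tid,
            )
            continue
        if prof[pos] < 1:
            continue
        cat = classify_category(prof, pos)
        rows.append(
            {
                "mirna_id": r["mirna_id"],
                "transcript_id": tid,
                "site_start": int(r.get("site_start", -1)),
                "site_end": int(r["site_end"]),
                "position": pos,
                "depth": int(prof[pos]),
                "category": cat,
                "confirmed": cat in keep,
            }
        )
    cols = ["mirna_id", "transcript_id", "site_start", "site_end",
            "position", "depth", "category", "confirmed"]
    return pd.DataFrame(rows, columns=cols)
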