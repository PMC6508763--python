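"""Duplicate-file detection by content hashing.

Meta-analyses that pool thousands of array files can silently include the
same raw file under different names, which biases any downstream
statistics.  Files are treated as opaque bytes and grouped by digest
(MD5 by default; SHA-256 offered): byte-identical files match regardless
of name.  ``duplicate_count`` counts *redundant copies* — group size minus
one, summed — so removing them from N scanned files leaves
``N - duplicate_count`` unique files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = ["ALGORITHMS", "DuplicateGroup", "DuplicateReport", "hash_files", "find_duplicates"]

ALGORITHMS = ("md5", "sha256")

_CHUNK = 1 << 20


@dataclass(frozen=True)
class DuplicateGroup:
    digest: str
    paths: tuple[str, ...]  # lexicographically sorted, >= 2 members

    @property
    def size(self) -> int:
        return len(self.paths)


@dataclass(frozen=True)
class DuplicateReport:
    groups: tuple[DuplicateGroup, ...]
    total_files: int

    @property
    def duplicate_count(self) -> int:
        """Redundant copies: sum over groups of (group size - 1)."""
        return sum(g.size - 1 for g in self.groups)

    @property
    def unique_count(self) -> int:
        return self.total_files - self.duplicate_count


def hash_files(paths: Sequence, algorithm: str = "md5") -> dict[str, str]:
    """Streaming content digest of each file; path -> hex digest.

    Raises ``FileNotFoundError`` / ``OSError`` naming the unreadable path.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    digests: dict[str, str] = {}
    for path in paths:
        h = hashlib.new(algorithm)
        try:
            with open(path, "rb") as fh:
                while chunk := fh.read(_CHUNK):
                    h.update(chunk)
        except OSError as exc:
            raise type(exc)(f"cannot read {path}: {exc}") from exc
        digests[str(path)] = h.hexdigest()
    return digests


def find_duplicates(paths: Sequence, algorithm: str = "md5") -> DuplicateReport:
    """Group byte-identical files; deterministic in the input path order.

    Groups are ordered by digest, members lexicographically by path.
    """
    digests = hash_files(paths, algorithm=algorithm)
    by_digest: dict[str, list[str]] = {}
    for path, digest in digests.items():
        by_digest.setdefault(digest, []).append(path)
    groups = tuple(
        DuplicateGroup(digest=d, paths=tuple(sorted(members)))
        for d, members in sorted(by_digest.items())
        if len(members) >= 2
    )
    return DuplicateReport(groups=groups, total_files=len(digests))


def write_duplicate_report(report: DuplicateReport, path, comments: Iterable[str] = ()) -> None:
    """TSV report: digest, group_size, member_paths (semicolon-joined)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("digest\tgroup_size\tmember_paths\n")
        for g in report.groups:
            fh.write(f"{g.digest}\t{g.size}\t" + ";".join(g.paths) + "\n")
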