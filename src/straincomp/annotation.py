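"""CDS annotation records and minimal GFF3 reading/writing.

Only the subset of GFF3 this pipeline consumes is handled: CDS features
with ``ID``, ``product``, optional ``category`` and ``ec_number``
attributes.  GFF3 coordinates are 1-based inclusive on disk; records are
converted to the library's 0-based half-open convention in memory.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import List, Optional

__all__ = ["CdsRecord", "read_gff3", "write_gff3"]

HYPOTHETICAL = "hypothetical protein"


@dataclass
class CdsRecord:
    cds_id: str
    replicon: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    product: str = HYPOTHETICAL
    category: Optional[str] = None
    ec_numbers: List[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_hypothetical(self) -> bool:
        return HYPOTHETICAL in self.product.lower()


def _fmt_attrs(cds: CdsRecord) -> str:
    parts = [f"ID={urllib.parse.quote(cds.cds_id)}",
             f"product={urllib.parse.quote(cds.product)}"]
    if cds.category:
        parts.append(f"category={urllib.parse.quote(cds.category)}")
    if cds.ec_numbers:
        parts.append("ec_number=" + ",".join(cds.ec_numbers))
    return ";".join(parts)


def write_gff3(records: List[CdsRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cds in records:
            fh.write(
                "\t".join(
                    [
                        cds.replicon,
                        "straincomp",
                        "CDS",
                        str(cds.start + 1),
                        str(cds.end),
                        ".",
                        cds.strand,
                        "0",
                        _fmt_attrs(cds),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> List[CdsRecord]:
    records: List[CdsRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            if fields[2] != "CDS":
                continue
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = urllib.parse.unquote(v)
            ecs = [e for e in attrs.get("ec_number", "").split(",") if e]
            records.append(
                CdsRecord(
                    cds_id=attrs.get("ID", f"cds{lineno}"),
                    replicon=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    product=attrs.get("product", ""),
                    category=attrs.get("category") or None,
                    ec_numbers=ecs,
                )
            )
    return records
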