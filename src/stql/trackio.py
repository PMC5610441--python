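"""Reading and writing signal tracks.

On-disk conventions differ from the engine's internal one: BED and
bedGraph are 0-based half-open, WIG is 1-based inclusive.  Internally
everything is 1-based both-ends-inclusive, so BED/bedGraph loading maps
``start_disk + 1 .. end_disk`` and writing inverts that.  BED carries
no signal value (value stays NULL; the score column is metadata).  The
internal TSV dump is a lossless header-bearing tab-separated format.
"""

from __future__ import annotations

import os
from typing import Optional

import yaml

from .model import Catalog, GenomicInterval, StqlError, Track, TrackSchema

FORMATS = ("bed", "bedgraph", "wig", "tsv")

_EXTENSIONS = {
    ".bed": "bed",
    ".bedgraph": "bedgraph",
    ".bg": "bedgraph",
    ".wig": "wig",
    ".tsv": "tsv",
    ".txt": "tsv",
}


class TrackIOError(StqlError):
    pass


def infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    try:
        return _EXTENSIONS[ext]
    except KeyError:
        raise TrackIOError(
            f"cannot infer track format from extension of {path!r}"
        ) from None


def read_track(path: str, fmt: Optional[str] = None,
               name: Optional[str] = None) -> Track:
    """Load a track file into internal 1-based inclusive coordinates."""
    fmt = (fmt or infer_format(path)).lower()
    if fmt not in FORMATS:
        raise TrackIOError(f"unsupported format {fmt!r}")
    name = name or os.path.splitext(os.path.basename(path))[0]
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if fmt == "bed":
        return _parse_bed(lines, name, path)
    if fmt == "bedgraph":
        return _parse_bedgraph(lines, name, path)
    if fmt == "wig":
        return _parse_wig(lines, name, path)
    return _parse_tsv(lines, name, path)


def _skippable(line: str) -> bool:
    s = line.strip()
    return (not s or s.startswith("#") or s.startswith("track")
            or s.startswith("browser"))


def _convert_disk_coords(start_s: str, end_s: str, path: str, ln: int):
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise TrackIOError(
            f"{path}:{ln}: non-integer coordinates"
        ) from None
    if end <= start:
        raise TrackIOError(f"{path}:{ln}: end <= start on disk")
    return start + 1, end  # 0-based half-open -> 1-based inclusive


_BED_EXTRA = (("name", "string"), ("score", "float"), ("strand", "string"))


def _parse_bed(lines, name, path) -> Track:
    intervals = []
    max_extra = 0
    for ln, line in enumerate(lines, 1):
        if _skippable(line):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise TrackIOError(f"{path}:{ln}: BED needs >= 3 columns")
        start, end = _convert_disk_coords(cols[1], cols[2], path, ln)
        meta = {}
        if len(cols) > 3:
            meta["name"] = cols[3]
        if len(cols) > 4:
            try:
                meta["score"] = float(cols[4])
            except ValueError:
                raise TrackIOError(f"{path}:{ln}: non-numeric score") from None
        if len(cols) > 5:
            meta["strand"] = cols[5]
        max_extra = max(max_extra, len(cols) - 3)
        intervals.append(GenomicInterval(cols[0], start, end, None, meta))
    extra = _BED_EXTRA[: min(max_extra, 3)]
    return Track(name, intervals, schema=TrackSchema.default(extra))


def _parse_bedgraph(lines, name, path) -> Track:
    intervals = []
    for ln, line in enumerate(lines, 1):
        if _skippable(line):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 4:
            raise TrackIOError(f"{path}:{ln}: bedGraph needs 4 columns")
        start, end = _convert_disk_coords(cols[1], cols[2], path, ln)
        try:
            value = float(cols[3])
        except ValueError:
            raise TrackIOError(f"{path}:{ln}: non-numeric value") from None
        intervals.append(GenomicInterval(cols[0], start, end, value))
    return Track(name, intervals, schema=TrackSchema.default())


def _parse_wig(lines, name, path) -> Track:
    intervals = []
    mode = None  # ("fixed", chrom, next_start, step, span) | ("var", chrom, span)
    for ln, line in enumerate(lines, 1):
        s = line.strip()
        if not s or s.startswith("#") or s.startswith("track") \
                or s.startswith("browser"):
            continue
        if s.startswith("fixedStep") or s.startswith("variableStep"):
            fields = dict(
                kv.split("=", 1) for kv in s.split()[1:] if "=" in kv
            )
            if "chrom" not in fields:
                raise TrackIOError(f"{path}:{ln}: declaration lacks chrom")
            span = int(fields.get("span", 1))
            if s.startswith("fixedStep"):
                if "start" not in fields:
                    raise TrackIOError(f"{path}:{ln}: fixedStep lacks start")
                step = int(fields.get("step", span))
                mode = ["fixed", fields["chrom"], int(fields["start"]), step, span]
            else:
                mode = ["var", fields["chrom"], span]
            continue
        if mode is None:
            raise TrackIOError(f"{path}:{ln}: data before step declaration")
        if mode[0] == "fixed":
            _kind, chrom, nxt, step, span = mode
            try:
                value = float(s)
            except ValueError:
                raise TrackIOError(f"{path}:{ln}: bad fixedStep value") from None
            intervals.append(
                GenomicInterval(chrom, nxt, nxt + span - 1, value)
            )
            mode[2] = nxt + step
        else:
            _kind, chrom, span = mode
            cols = s.split()
            if len(cols) != 2:
                raise TrackIOError(f"{path}:{ln}: variableStep needs 2 columns")
            try:
                pos, value = int(cols[0]), float(cols[1])
            except ValueError:
                raise TrackIOError(f"{path}:{ln}: bad variableStep row") from None
            intervals.append(
                GenomicInterval(chrom, pos, pos + span - 1, value)
            )
    return Track(name, intervals, schema=TrackSchema.default())


_TSV_TYPE_LINE = "##types"


def _parse_tsv(lines, name, path) -> Track:
    """Internal dump: optional '##types <t1> <t2> ...' line, then a
    header row of attribute names, then rows; 1-based inclusive."""
    types = None
    rows = []
    header = None
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.startswith(_TSV_TYPE_LINE):
            types = line.split("\t")[1:]
            continue
        if line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if header is None:
            header = cols
            continue
        if len(cols) != len(header):
            raise TrackIOError(f"{path}:{ln}: column count mismatch")
        rows.append((ln, cols))
    if header is None:
        raise TrackIOError(f"{path}: empty TSV track dump")
    lower = [h.lower() for h in header]
    for req in ("chr", "chrstart", "chrend", "value"):
        if req not in lower:
            raise TrackIOError(f"{path}: TSV header lacks {req!r}")
    if types is None:
        types = [
            "string" if h in ("chr",) else
            "int" if h in ("chrstart", "chrend") else
            "float" if h == "value" else "string"
            for h in lower
        ]
    schema = TrackSchema(
        [(h if lower[k] not in ("chr", "chrstart", "chrend", "value")
          else lower[k], t)
         for k, (h, t) in enumerate(zip(header, types))]
    )
    intervals = []
    for ln, cols in rows:
        rec = {}
        for h, t, c in zip(lower, types, cols):
            if c == "NULL":
                rec[h] = None
            elif t == "int":
                rec[h] = int(c)
            elif t == "float":
                rec[h] = float(c)
            else:
                rec[h] = c
        meta = {
            header[k]: rec[lower[k]]
            for k in range(len(header))
            if lower[k] not in ("chr", "chrstart", "chrend", "value")
            and rec[lower[k]] is not None
        }
        try:
            intervals.append(
                GenomicInterval(rec["chr"], rec["chrstart"], rec["chrend"],
                                rec["value"], meta)
            )
        except (ValueError, TypeError) as exc:
            raise TrackIOError(f"{path}:{ln}: {exc}") from None
    return Track(name, intervals, schema=schema)


def _fmt_value(v) -> str:
    if v is None:
        return "NULL"
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def write_track(t: Track, path: str, fmt: Optional[str] = None) -> None:
    """Write a track; TSV is lossless, BED/bedGraph convert coordinates
    back to 0-based half-open."""
    fmt = (fmt or infer_format(path)).lower()
    ivs = t.sorted_intervals()
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "tsv":
            names = t.schema.names
            types = [t.schema.type_of(n) for n in names]
            fh.write(_TSV_TYPE_LINE + "\t" + "\t".join(types) + "\n")
            fh.write("\t".join(names) + "\n")
            for iv in ivs:
                fh.write(
                    "\t".join(_fmt_value(iv.get(n)) for n in names) + "\n"
                )
        elif fmt == "bedgraph":
            for iv in ivs:
                if iv.value is None:
                    raise TrackIOError(
                        "bedGraph cannot represent NULL values"
                    )
                fh.write(
                    f"{iv.chr}\t{iv.chrstart - 1}\t{iv.chrend}\t"
                    f"{_fmt_value(iv.value)}\n"
                )
        elif fmt == "bed":
            has_strand = any(iv.metadata.get("strand") for iv in ivs)
            for iv in ivs:
                cols = [iv.chr, str(iv.chrstart - 1), str(iv.chrend)]
                if has_strand:
                    cols += [
                        str(iv.metadata.get("name", ".")),
                        _fmt_value(iv.metadata.get("score", 0)),
                        str(iv.metadata.get("strand", ".")),
                    ]
                elif "name" in iv.metadata or "score" in iv.metadata:
                    cols.append(str(iv.metadata.get("name", ".")))
                    if "score" in iv.metadata:
                        cols.append(_fmt_value(iv.metadata["score"]))
                fh.write("\t".join(cols) + "\n")
        else:
            raise TrackIOError(f"cannot write format {fmt!r}")


def read_chrom_sizes(path: str) -> dict[str, int]:
    """UCSC chrom.sizes dialect: 'chrom<TAB>length' per line; '#'
    comment lines are skipped."""
    sizes: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            cols = s.split()
            if len(cols) < 2:
                raise TrackIOError(f"{path}:{ln}: expected two columns")
            chrom = cols[0]
            if chrom in sizes:
                raise TrackIOError(f"{path}:{ln}: duplicate chromosome {chrom}")
            try:
                sizes[chrom] = int(cols[1])
            except ValueError:
                raise TrackIOError(
                    f"{path}:{ln}: non-integer length {cols[1]!r}"
                ) from None
    return sizes


def load_catalog(path: str) -> Catalog:
    """Build a catalog from a YAML file.

    Layout::

        tracks:
          - name: peaks_gm12878
            path: peaks_gm12878.bed      # relative to the catalog file
            format: bed                  # optional; inferred otherwise
            category: TFBS
            attributes: {cell: GM12878}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(path))
    cat = Catalog()
    for entry in doc.get("tracks", []):
        track_path = entry["path"]
        if not os.path.isabs(track_path):
            track_path = os.path.join(base, track_path)
        track = read_track(
            track_path, fmt=entry.get("format"), name=entry["name"]
        )
        track.category = entry.get("category")
        track.track_attributes = dict(entry.get("attributes", {}))
        cat.add(track)
    return cat
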