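"""Two-step dataset de-identification.

Step one replaces genotype identifiers with colornames drawn from a fixed
palette and records the assignment in a master mapping file. Step two strips
identifying metadata: extra manifest columns (geo-tags, timestamps, free text)
and embedded image metadata (EXIF/XMP/comments), leaving pixel data untouched.

The master map is written to a *different* directory than the de-identified
manifest; keeping the two apart (plus the original data) is an organizational
control, but the refusal to co-locate them is enforced here.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import random
from dataclasses import dataclass, replace
from typing import Iterable

from PIL import Image

from .manifest import Manifest, strip_extras

__all__ = [
    "DEFAULT_PALETTE",
    "DeidentificationMap",
    "build_map",
    "apply_map",
    "invert_map",
    "strip_image_metadata",
    "save_map",
    "load_map",
]

#: A fixed published palette of colornames (CSS basic + extended colours).
DEFAULT_PALETTE: tuple[str, ...] = (
    "Pink", "Red", "Azure", "Charcoal", "Scarlet", "Indigo", "Purple", "White",
    "Opal", "Ebony", "Bronze", "Orange", "Amber", "Emerald", "Copper", "Yellow",
    "Teal", "Beige", "Green", "Violet", "Crimson", "Cyan", "Blue", "Gray",
    "Turquoise", "Brown", "Black", "Magenta", "Olive", "Maroon", "Navy", "Coral",
    "Salmon", "Khaki", "Plum", "Orchid", "Sienna", "Ivory", "Lavender", "Mint",
)


@dataclass(frozen=True)
class DeidentificationMap:
    """Bijective genotype-identifier -> colorname assignment."""

    pairs: tuple[tuple[str, str], ...]
    created: str
    seed: int

    def __post_init__(self) -> None:
        genotypes = [g for g, _ in self.pairs]
        colors = [c for _, c in self.pairs]
        if len(set(genotypes)) != len(genotypes) or len(set(colors)) != len(colors):
            raise ValueError("de-identification map must be bijective")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def inverse_dict(self) -> dict[str, str]:
        return {c: g for g, c in self.pairs}


def build_map(
    genotypes: Iterable[str], palette: Iterable[str] = DEFAULT_PALETTE, seed: int = 0
) -> DeidentificationMap:
    """Assign each genotype a unique colorname, deterministically for a seed.

    The palette is shuffled with the seed and zipped against the sorted
    genotype identifiers, so the assignment is reproducible and auditable.
    """
    names = sorted(set(genotypes))
    pal = list(palette)
    if len(set(pal)) != len(pal):
        raise ValueError("palette contains duplicate colornames")
    if len(pal) < len(names):
        raise ValueError(
            f"palette too small: {len(pal)} colornames for {len(names)} genotypes"
        )
    rng = random.Random(seed)
    rng.shuffle(pal)
    created = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    return DeidentificationMap(tuple(zip(names, pal)), created=created, seed=seed)


def apply_map(manifest: Manifest, dmap: DeidentificationMap) -> Manifest:
    """Replace genotype identifiers with colornames and drop extra metadata columns.

    Every genotype present in the manifest must appear in the map; colornames
    produced by a previous pass are deliberately *not* mapped to themselves, so
    applying the map twice fails loudly instead of silently re-encoding.
    """
    table = dmap.as_dict()
    missing = sorted({r.genotype for r in manifest.records} - table.keys())
    if missing:
        raise ValueError(f"genotypes not present in de-identification map: {', '.join(missing)}")
    renamed = Manifest(
        tuple(replace(r, genotype=table[r.genotype]) for r in manifest.records)
    )
    return strip_extras(renamed)


def invert_map(manifest: Manifest, dmap: DeidentificationMap) -> Manifest:
    """Recover the original genotype identifiers using the master map."""
    table = dmap.inverse_dict()
    missing = sorted({r.genotype for r in manifest.records} - table.keys())
    if missing:
        raise ValueError(f"colornames not present in de-identification map: {', '.join(missing)}")
    return Manifest(tuple(replace(r, genotype=table[r.genotype]) for r in manifest.records))


# JPEG markers that may carry identifying metadata (EXIF/XMP/ICC/comments).
# APP0 (JFIF) and APP14 (Adobe colour transform) are kept: both affect decoding
# and carry no acquisition metadata.
_JPEG_KEEP_APP = {0xE0, 0xEE}


def _strip_jpeg_segments(data: bytes) -> bytes:
    """Remove APPn (except JFIF/Adobe) and COM segments from a JPEG byte stream.

    Operates on the compressed stream directly so pixel data is bit-identical.
    """
    if data[:2] != b"\xff\xd8":
        raise ValueError("not a JPEG stream")
    out = bytearray(b"\xff\xd8")
    i = 2
    n = len(data)
    while i < n:
        if data[i] != 0xFF:
            raise ValueError("corrupt JPEG stream")
        marker = data[i + 1]
        if marker == 0xDA:  # start of scan: copy the rest verbatim
            out.extend(data[i:])
            break
        seg_len = int.from_bytes(data[i + 2 : i + 4], "big")
        seg = data[i : i + 2 + seg_len]
        is_app = 0xE0 <= marker <= 0xEF
        if (is_app and marker not in _JPEG_KEEP_APP) or marker == 0xFE:
            pass  # drop
        else:
            out.extend(seg)
        i += 2 + seg_len
    return bytes(out)


# PNG ancillary chunks that can carry text/EXIF/timestamps.
_PNG_DROP_CHUNKS = {b"tEXt", b"zTXt", b"iTXt", b"eXIf", b"tIME"}
_PNG_SIG = b"\x89PNG\r\n\x1a\n"


def _strip_png_chunks(data: bytes) -> bytes:
    if data[:8] != _PNG_SIG:
        raise ValueError("not a PNG stream")
    out = bytearray(_PNG_SIG)
    i = 8
    while i < len(data):
        length = int.from_bytes(data[i : i + 4], "big")
        ctype = data[i + 4 : i + 8]
        chunk = data[i : i + 12 + length]
        if ctype not in _PNG_DROP_CHUNKS:
            out.extend(chunk)
        i += 12 + length
        if ctype == b"IEND":
            break
    return bytes(out)


def strip_image_metadata(image_path_in: str, image_path_out: str) -> None:
    """Copy an image dropping EXIF/XMP/GPS/timestamp metadata, pixels unchanged.

    JPEG and PNG streams are rewritten segment/chunk-wise (no re-encoding),
    so the compressed pixel data is preserved bit-for-bit.
    """
    with open(image_path_in, "rb") as fh:
        data = fh.read()
    if data[:2] == b"\xff\xd8":
        stripped = _strip_jpeg_segments(data)
    elif data[:8] == _PNG_SIG:
        stripped = _strip_png_chunks(data)
    else:
        raise ValueError(f"{image_path_in}: not a JPEG or PNG image")
    # sanity: output must still decode
    from io import BytesIO

    Image.open(BytesIO(stripped)).verify()
    with open(image_path_out, "wb") as fh:
        fh.write(stripped)


def save_map(dmap: DeidentificationMap, map_dir: str, manifest_dir: str | None = None) -> str:
    """Write the master map (CSV + JSON sidecar with seed and creation time).

    Refuses to write into the same directory as the de-identified manifest.
    Returns the CSV path.
    """
    if manifest_dir is not None:
        if os.path.realpath(map_dir) == os.path.realpath(manifest_dir):
            raise ValueError(
                "master map must not be stored alongside the de-identified manifest; "
                "choose a separate directory"
            )
    os.makedirs(map_dir, exist_ok=True)
    csv_path = os.path.join(map_dir, "deidentification_map.csv")
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        fh.write("genotype,colorname\n")
        for g, c in dmap.pairs:
            fh.write(f"{g},{c}\n")
    with open(os.path.join(map_dir, "deidentification_map.json"), "w", encoding="utf-8") as fh:
        json.dump({"seed": dmap.seed, "created": dmap.created}, fh, indent=2)
    return csv_path


def load_map(map_dir: str) -> DeidentificationMap:
    csv_path = os.path.join(map_dir, "deidentification_map.csv")
    with open(csv_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pairs = tuple(tuple(line.split(",", 1)) for line in lines[1:] if line)
    with open(os.path.join(map_dir, "deidentification_map.json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    return DeidentificationMap(pairs, created=meta["created"], seed=meta["seed"])
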