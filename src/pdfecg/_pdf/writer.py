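"""Minimal PDF 1.4 writer for vector ECG pages.

Emits a well-formed single- or multi-page document containing stroked paths
(polylines, rectangles, cubic beziers), Helvetica text and — for negative
test fixtures — an embedded raster image.  Content streams are FlateDecode
compressed by default.  This is a renderer for machine-generated report
pages, not a general typesetting library.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PdfWriter", "PageBuilder"]

# approximate Helvetica metrics (fraction of font size) used for text bboxes;
# the reader uses the same numbers so writer/reader geometry agrees
CHAR_WIDTH = 0.556
ASCENT = 0.718
DESCENT = 0.207


def text_bbox(text: str, x: float, y: float, size: float) -> tuple[float, float, float, float]:
    """Axis-aligned bbox of a Helvetica string shown at baseline origin (x, y)."""
    return (x, y - DESCENT * size, x + CHAR_WIDTH * size * len(text), y + ASCENT * size)


def _fmt(v: float) -> str:
    s = f"{v:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


@dataclass
class _Path:
    points: np.ndarray          # (n, 2) user-space polyline vertices
    width: float = 1.0


@dataclass
class _Rect:
    x: float
    y: float
    w: float
    h: float
    width: float = 1.0


@dataclass
class _Bezier:
    # (1 + 3k, 2): start point followed by control triples
    points: np.ndarray
    width: float = 1.0


@dataclass
class _Text:
    text: str
    x: float
    y: float
    size: float


@dataclass
class PageBuilder:
    """Accumulates drawing commands for one page."""

    width: float = 595.0
    height: float = 842.0
    _cmds: list = field(default_factory=list)
    _has_image: bool = False

    def add_polyline(self, points, stroke_width: float = 0.8) -> int:
        """Add one stroked polyline path; returns its path index on the page."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("polyline needs an (n>=2, 2) point array")
        self._cmds.append(_Path(pts, stroke_width))
        return self.n_paths - 1

    def add_rect(self, x: float, y: float, w: float, h: float, stroke_width: float = 1.0) -> int:
        self._cmds.append(_Rect(x, y, w, h, stroke_width))
        return self.n_paths - 1

    def add_bezier(self, points, stroke_width: float = 0.8) -> int:
        pts = np.asarray(points, dtype=float)
        if (pts.shape[0] - 1) % 3 != 0 or pts.shape[0] < 4:
            raise ValueError("bezier needs 1 + 3k control points")
        self._cmds.append(_Bezier(pts, stroke_width))
        return self.n_paths - 1

    def add_text(self, text: str, x: float, y: float, size: float = 8.0) -> None:
        if not text:
            raise ValueError("empty text")
        self._cmds.append(_Text(text, x, y, size))

    def add_raster_stub(self) -> None:
        """Embed a tiny grayscale image (negative fixture for raster-only pages)."""
        self._has_image = True

    @property
    def n_paths(self) -> int:
        return sum(1 for c in self._cmds if not isinstance(c, _Text))

    # -- content stream -----------------------------------------------------

    def _content(self) -> bytes:
        out: list[str] = []
        for cmd in self._cmds:
            if isinstance(cmd, _Path):
                out.append(f"{_fmt(cmd.width)} w")
                p = cmd.points
                out.append(f"{_fmt(p[0, 0])} {_fmt(p[0, 1])} m")
                out.extend(f"{_fmt(x)} {_fmt(y)} l" for x, y in p[1:])
                out.append("S")
            elif isinstance(cmd, _Rect):
                out.append(f"{_fmt(cmd.width)} w")
                out.append(f"{_fmt(cmd.x)} {_fmt(cmd.y)} {_fmt(cmd.w)} {_fmt(cmd.h)} re S")
            elif isinstance(cmd, _Bezier):
                out.append(f"{_fmt(cmd.width)} w")
                p = cmd.points
                out.append(f"{_fmt(p[0, 0])} {_fmt(p[0, 1])} m")
                for k in range(1, p.shape[0], 3):
                    coords = " ".join(_fmt(v) for v in p[k:k + 3].ravel())
                    out.append(f"{coords} c")
                out.append("S")
            elif isinstance(cmd, _Text):
                esc = cmd.text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
                out.append(
                    f"BT /F1 {_fmt(cmd.size)} Tf {_fmt(cmd.x)} {_fmt(cmd.y)} Td ({esc}) Tj ET"
                )
        if self._has_image:
            out.append(f"q {_fmt(self.width)} 0 0 {_fmt(self.height)} 0 0 cm /Im1 Do Q")
        return ("\n".join(out) + "\n").encode("latin-1")


class PdfWriter:
    """Builds and serializes a multi-page PDF document."""

    def __init__(self, compress: bool = True, encrypt_stub: bool = False):
        self.pages: list[PageBuilder] = []
        self.compress = compress
        # writes an /Encrypt entry in the trailer (content is NOT actually
        # encrypted) so readers that refuse protected files can be tested
        self.encrypt_stub = encrypt_stub

    def new_page(self, width: float = 595.0, height: float = 842.0) -> PageBuilder:
        page = PageBuilder(width, height)
        self.pages.append(page)
        return page

    def tobytes(self) -> bytes:
        objs: dict[int, bytes] = {}
        next_id = 1

        def reserve() -> int:
            nonlocal next_id
            oid = next_id
            next_id += 1
            return oid

        catalog_id = reserve()
        pages_id = reserve()
        font_id = reserve()
        any_image = any(p._has_image for p in self.pages)
        image_id = reserve() if any_image else None

        page_ids = []
        for page in self.pages:
            pid = reserve()
            cid = reserve()
            page_ids.append((pid, cid, page))

        objs[catalog_id] = f"<< /Type /Catalog /Pages {pages_id} 0 R >>".encode()
        kids = " ".join(f"{pid} 0 R" for pid, _, _ in page_ids)
        objs[pages_id] = (
            f"<< /Type /Pages /Kids [{kids}] /Count {len(page_ids)} >>".encode()
        )
        objs[font_id] = (
            b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>"
        )
        if image_id is not None:
            img = bytes([0, 64, 128, 255])  # 2x2 gray
            objs[image_id] = (
                b"<< /Type /XObject /Subtype /Image /Width 2 /Height 2 "
                b"/ColorSpace /DeviceGray /BitsPerComponent 8 /Length 4 >>\n"
                b"stream\n" + img + b"\nendstream"
            )

        for pid, cid, page in page_ids:
            data = page._content()
            if self.compress:
                data = zlib.compress(data)
                filt = b"/Filter /FlateDecode "
            else:
                filt = b""
            objs[cid] = (
                b"<< " + filt + f"/Length {len(data)} >>\n".encode()
                + b"stream\n" + data + b"\nendstream"
            )
            res = f"/Font << /F1 {font_id} 0 R >>"
            if page._has_image:
                res += f" /XObject << /Im1 {image_id} 0 R >>"
            objs[pid] = (
                f"<< /Type /Page /Parent {pages_id} 0 R "
                f"/MediaBox [0 0 {_fmt(page.width)} {_fmt(page.height)}] "
                f"/Resources << {res} >> /Contents {cid} 0 R >>"
            ).encode()

        buf = bytearray(b"%PDF-1.4\n%\xe2\xe3\xcf\xd3\n")
        offsets = {}
        for oid in sorted(objs):
            offsets[oid] = len(buf)
            buf += f"{oid} 0 obj\n".encode() + objs[oid] + b"\nendobj\n"
        xref_off = len(buf)
        n = max(objs) + 1
        buf += f"xref\n0 {n}\n".encode()
        buf += b"0000000000 65535 f \n"
        for oid in range(1, n):
            buf += f"{offsets[oid]:010d} 00000 n \n".encode()
        trailer = f"<< /Size {n} /Root {catalog_id} 0 R"
        if self.encrypt_stub:
            trailer += " /Encrypt << /V 1 >>"
        trailer += " >>"
        buf += b"trailer\n" + trailer.encode() + b"\n"
        buf += f"startxref\n{xref_off}\n%%EOF\n".encode()
        return bytes(buf)

    def write(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.tobytes())
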