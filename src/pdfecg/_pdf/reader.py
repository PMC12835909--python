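"""Content-stream parser recovering vector paths and text from PDF pages.

Handles the drawing subset that ECG report generators emit: polyline and
bezier path construction (``m l c re h``), stroke/fill painting, the graphics
state stack with ``cm`` transforms, and simple-font text showing (``Tf Td TD
Tm Tj TJ``).  Streams may be plain or FlateDecode.  Bezier segments are
flattened to polylines at a fixed chord tolerance so every recovered path is
a point sequence in page coordinates (y-up, 1/72-inch units).
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np

from pdfecg.errors import DocumentError, RasterPageError
from pdfecg._pdf.writer import text_bbox

__all__ = ["RawPath", "RawText", "RawPage", "read_pages"]

BEZIER_CHORD_TOL = 0.05  # page units; flattening tolerance for curve ops


@dataclass
class RawPath:
    """One painted subpath: ordered vertices plus its source path object index."""

    points: np.ndarray        # (n, 2)
    path_index: int           # index of the painting op on the page
    subpath_index: int
    stroke_width: float


@dataclass
class RawText:
    text: str
    x: float                  # baseline origin
    y: float
    size: float

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return text_bbox(self.text, self.x, self.y, self.size)


@dataclass
class RawPage:
    width: float
    height: float
    paths: list[RawPath] = field(default_factory=list)
    texts: list[RawText] = field(default_factory=list)
    has_image: bool = False


# ---------------------------------------------------------------------------
# document-level parsing

_OBJ_RE = re.compile(rb"(\d+)\s+\d+\s+obj\b", re.S)
_NUM_RE = re.compile(r"[-+]?\d*\.?\d+")


def _body_at(data: bytes, offset: int) -> tuple[int, bytes] | None:
    """Parse one ``N G obj ... endobj`` at a byte offset, honouring /Length.

    Binary stream content may contain any byte pattern, so the stream extent
    is taken from the declared /Length rather than by searching for markers.
    """
    m = re.compile(rb"(\d+)\s+\d+\s+obj\b").match(data, offset)
    if m is None:
        return None
    oid = int(m.group(1))
    start = m.end()
    d = _dict_of(data[start:start + 4096])
    sm = re.compile(rb"\s*stream\r?\n").match(data, start + _dict_end(data, start))
    if d and sm is not None:
        lm = re.search(rb"/Length\s+(\d+)\b", d)
        if lm:
            s0 = sm.end()
            s1 = s0 + int(lm.group(1))
            end = data.find(b"endobj", s1)
            return oid, data[start:end if end != -1 else len(data)]
    end = data.find(b"endobj", start)
    return oid, data[start:end if end != -1 else len(data)]


def _dict_end(data: bytes, start: int) -> int:
    """Length of the dictionary beginning at/after ``start`` (0 if none)."""
    i = data.find(b"<<", start, start + 64)
    if i == -1:
        return 0
    depth = 0
    for j in range(i, len(data) - 1):
        pair = data[j:j + 2]
        if pair == b"<<":
            depth += 1
        elif pair == b">>":
            depth -= 1
            if depth == 0:
                return j + 2 - start
    return 0


def _object_map(data: bytes) -> dict[int, bytes]:
    """Map object number -> raw object body (between obj and endobj)."""
    objs: dict[int, bytes] = {}
    # preferred route: xref table offsets (robust to binary stream content)
    sx = data.rfind(b"startxref")
    if sx != -1:
        m = re.search(rb"startxref\s+(\d+)", data[sx:])
        if m:
            xref_at = int(m.group(1))
            tm = re.compile(rb"xref\s+(\d+)\s+(\d+)\s*").match(data, xref_at)
            if tm:
                first, count = int(tm.group(1)), int(tm.group(2))
                pos = tm.end()
                for k in range(count):
                    row = data[pos + 20 * k: pos + 20 * (k + 1)]
                    rm = re.match(rb"(\d{10}) (\d{5}) ([nf])", row)
                    if rm is None:
                        break
                    if rm.group(3) == b"n":
                        parsed = _body_at(data, int(rm.group(1)))
                        if parsed is not None:
                            objs[parsed[0]] = parsed[1]
    if not objs:
        # fallback: linear scan (may misfire inside binary streams, but those
        # documents at least become partially readable)
        for m in _OBJ_RE.finditer(data):
            parsed = _body_at(data, m.start())
            if parsed is not None and parsed[0] not in objs:
                objs[parsed[0]] = parsed[1]
    if not objs:
        raise DocumentError("no PDF objects found")
    return objs


def _dict_of(body: bytes) -> bytes:
    i = body.find(b"<<")
    if i == -1:
        return b""
    depth = 0
    for j in range(i, len(body) - 1):
        if body[j:j + 2] == b"<<":
            depth += 1
        elif body[j:j + 2] == b">>":
            depth -= 1
            if depth == 0:
                return body[i:j + 2]
    return body[i:]


def _stream_of(body: bytes) -> bytes | None:
    m = re.search(rb"stream\r?\n", body)
    if m is None:
        return None
    d = _dict_of(body)
    lm = re.search(rb"/Length\s+(\d+)\b", d)
    if lm:
        # exact extent: compressed data may itself end in newline bytes
        raw = body[m.end():m.end() + int(lm.group(1))]
    else:
        end = body.rfind(b"endstream")
        raw = body[m.end():end]
        if raw.endswith(b"\r\n"):
            raw = raw[:-2]
        elif raw.endswith(b"\n"):
            raw = raw[:-1]
    if b"/FlateDecode" in d:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:  # pragma: no cover - corrupt stream
            raise DocumentError(f"cannot inflate content stream: {exc}") from exc
    return raw


def _refs(d: bytes, key: bytes) -> list[int]:
    m = re.search(re.escape(key) + rb"\s*(\[[^\]]*\]|\d+\s+\d+\s+R)", d)
    if m is None:
        return []
    return [int(x) for x in re.findall(rb"(\d+)\s+\d+\s+R", m.group(1))]


def read_pages(source) -> list[RawPage]:
    """Parse a PDF given as a filesystem path or bytes; returns all pages in order."""
    if isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    if not data.startswith(b"%PDF-"):
        raise DocumentError("not a PDF: missing %PDF header")
    trailer_at = data.rfind(b"trailer")
    if trailer_at != -1 and b"/Encrypt" in data[trailer_at:]:
        raise DocumentError("document is encrypted")

    objs = _object_map(data)
    dicts = {oid: _dict_of(body) for oid, body in objs.items()}

    # page order via the page-tree Kids array; fall back to object order
    page_ids: list[int] = []
    for oid, d in dicts.items():
        if re.search(rb"/Type\s*/Pages\b", d):
            page_ids.extend(_refs(d, b"/Kids"))
    if not page_ids:
        page_ids = [oid for oid, d in dicts.items() if re.search(rb"/Type\s*/Page\b", d)
                    and not re.search(rb"/Type\s*/Pages\b", d)]
    if not page_ids:
        raise DocumentError("document has no pages")

    pages = []
    for pid in page_ids:
        d = dicts.get(pid)
        if d is None:
            raise DocumentError(f"missing page object {pid}")
        mb = re.search(rb"/MediaBox\s*\[([^\]]*)\]", d)
        if mb:
            nums = [float(x) for x in _NUM_RE.findall(mb.group(1).decode("latin-1"))]
            width, height = nums[2] - nums[0], nums[3] - nums[1]
        else:
            width, height = 612.0, 792.0
        page = RawPage(width=width, height=height)

        for cid in _refs(d, b"/Contents"):
            body = objs.get(cid)
            if body is None:
                continue
            stream = _stream_of(body)
            if stream is not None:
                _run_content(stream.decode("latin-1"), page)

        # image XObjects referenced from this page's resources
        for xid in re.findall(rb"/XObject\s*<<([^>]*)>>", d):
            for ref in re.findall(rb"(\d+)\s+\d+\s+R", xid):
                xd = dicts.get(int(ref), b"")
                if re.search(rb"/Subtype\s*/Image\b", xd):
                    page.has_image = True
        pages.append(page)
    return pages


# ---------------------------------------------------------------------------
# content-stream interpreter

_TOKEN_RE = re.compile(
    r"""\(((?:\\.|[^\\()])*)\)     # literal string
      | <<|>>|\[|\]
      | /([^\s/\[\]()<>]+)         # name
      | ([-+]?\d*\.?\d+)           # number
      | ([A-Za-z'"*]+)             # operator
    """,
    re.X,
)


def _unescape(s: str) -> str:
    return re.sub(r"\\([nrtbf()\\])",
                  lambda m: {"n": "\n", "r": "\r", "t": "\t", "b": "\b",
                             "f": "\f"}.get(m.group(1), m.group(1)), s)


def _flatten_bezier(p0, p1, p2, p3, tol=BEZIER_CHORD_TOL):
    """Adaptive de Casteljau flattening; returns points excluding p0."""
    # flatness: control points within tol of the chord (2-D cross product)
    u = p3 - p0
    d1 = abs(u[0] * (p1 - p0)[1] - u[1] * (p1 - p0)[0])
    d2 = abs(u[0] * (p2 - p0)[1] - u[1] * (p2 - p0)[0])
    chord = np.hypot(*(p3 - p0)) + 1e-12
    if (d1 + d2) / chord < tol:
        return [p3]
    mid = lambda a, b: (a + b) / 2.0  # noqa: E731
    p01, p12, p23 = mid(p0, p1), mid(p1, p2), mid(p2, p3)
    p012, p123 = mid(p01, p12), mid(p12, p23)
    c = mid(p012, p123)
    return _flatten_bezier(p0, p01, p012, c, tol) + _flatten_bezier(c, p123, p23, p3, tol)


def _run_content(src: str, page: RawPage) -> None:
    ctm = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    stack: list[np.ndarray] = []
    line_width = 1.0

    def xform(x, y, m=None):
        a, b, c, d, e, f = ctm if m is None else m
        return np.array([a * x + c * y + e, b * x + d * y + f])

    subpaths: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    paint_index = 0

    in_text = False
    tm_x = tm_y = 0.0
    font_size = 1.0
    leading = 0.0

    operands: list = []

    def flush_path(paint: bool):
        nonlocal subpaths, current, paint_index
        if current:
            subpaths.append(current)
        if paint:
            emitted = 0
            for si, sp in enumerate(subpaths):
                if len(sp) >= 2:
                    page.paths.append(RawPath(np.array(sp), paint_index, si, line_width))
                    emitted += 1
            if subpaths:
                paint_index += 1
        subpaths, current = [], []

    for m in _TOKEN_RE.finditer(src):
        string, name, number, op = m.group(1), m.group(2), m.group(3), m.group(4)
        if string is not None:
            operands.append(_unescape(string))
            continue
        if name is not None:
            operands.append("/" + name)
            continue
        if number is not None:
            operands.append(float(number))
            continue
        if op is None:
            continue

        if op == "q":
            stack.append(ctm.copy())
        elif op == "Q":
            if stack:
                ctm = stack.pop()
        elif op == "cm" and len(operands) >= 6:
            a, b, c, d, e, f = operands[-6:]
            new = np.array([
                a * ctm[0] + b * ctm[2],
                a * ctm[1] + b * ctm[3],
                c * ctm[0] + d * ctm[2],
                c * ctm[1] + d * ctm[3],
                e * ctm[0] + f * ctm[2] + ctm[4],
                e * ctm[1] + f * ctm[3] + ctm[5],
            ])
            ctm = new
        elif op == "w" and operands:
            line_width = float(operands[-1])
        elif op == "m" and len(operands) >= 2:
            if current:
                subpaths.append(current)
            current = [xform(operands[-2], operands[-1])]
        elif op == "l" and len(operands) >= 2:
            current.append(xform(operands[-2], operands[-1]))
        elif op == "c" and len(operands) >= 6 and current:
            p0 = current[-1]
            p1 = xform(operands[-6], operands[-5])
            p2 = xform(operands[-4], operands[-3])
            p3 = xform(operands[-2], operands[-1])
            current.extend(_flatten_bezier(p0, p1, p2, p3))
        elif op == "v" and len(operands) >= 4 and current:
            p0 = current[-1]
            p2 = xform(operands[-4], operands[-3])
            p3 = xform(operands[-2], operands[-1])
            current.extend(_flatten_bezier(p0, p0, p2, p3))
        elif op == "y" and len(operands) >= 4 and current:
            p0 = current[-1]
            p1 = xform(operands[-4], operands[-3])
            p3 = xform(operands[-2], operands[-1])
            current.extend(_flatten_bezier(p0, p1, p3, p3))
        elif op == "h" and current:
            current.append(current[0].copy())
        elif op == "re" and len(operands) >= 4:
            x, y, w, h = operands[-4:]
            if current:
                subpaths.append(current)
                current = []
            corners = [(x, y), (x + w, y), (x + w, y + h), (x, y + h), (x, y)]
            subpaths.append([xform(px, py) for px, py in corners])
        elif op in ("S", "s", "f", "F", "f*", "B", "B*", "b", "b*"):
            flush_path(paint=True)
        elif op == "n":
            flush_path(paint=False)
        elif op == "BT":
            in_text = True
            tm_x = tm_y = 0.0
        elif op == "ET":
            in_text = False
        elif op == "Tf" and operands:
            font_size = float(operands[-1])
        elif op in ("Td", "TD") and len(operands) >= 2:
            tm_x += operands[-2]
            tm_y += operands[-1]
            if op == "TD":
                leading = -operands[-1]
        elif op == "TL" and operands:
            leading = float(operands[-1])
        elif op == "T*":
            tm_y -= leading
        elif op == "Tm" and len(operands) >= 6:
            tm_x, tm_y = operands[-2], operands[-1]
        elif op == "Tj" and operands and in_text:
            text = str(operands[-1])
            if text:
                pos = xform(tm_x, tm_y)
                page.texts.append(RawText(text, pos[0], pos[1], font_size))
        elif op == "TJ" and in_text:
            text = "".join(o for o in operands if isinstance(o, str) and not o.startswith("/"))
            if text:
                pos = xform(tm_x, tm_y)
                page.texts.append(RawText(text, pos[0], pos[1], font_size))
        operands = []

    flush_path(paint=False)


def require_vector_page(page: RawPage) -> RawPage:
    """Reject pages whose only content is a raster image."""
    if page.has_image and not page.paths:
        raise RasterPageError(
            "page stores the ECG as a pixel image; vector extraction impossible"
        )
    return page
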