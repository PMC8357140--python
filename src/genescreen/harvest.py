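"""Offline supplementary-link extraction from saved article HTML.

Stand-in for a crawling stage: given pre-saved article pages, pull out the
hrefs pointing at .xls/.xlsx supplementary files.  No network code.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

from bs4 import BeautifulSoup

logger = logging.getLogger(__name__)

__all__ = ["HtmlParseError", "extract_supp_links", "extract_supp_links_from_file"]

_SUFFIXES = (".xls", ".xlsx")


class HtmlParseError(ValueError):
    """Saved page could not be decoded as text."""


def extract_supp_links(html: str) -> list[str]:
    """Hrefs ending in .xls or .xlsx (case-insensitive), deduplicated,
    in document order."""
    soup = BeautifulSoup(html, "html.parser")
    seen: set[str] = set()
    links: list[str] = []
    for anchor in soup.find_all("a", href=True):
        href = anchor["href"].strip()
        trimmed = href.split("?", 1)[0].split("#", 1)[0]
        if trimmed.lower().endswith(_SUFFIXES) and href not in seen:
            seen.add(href)
            links.append(href)
    return links


def extract_supp_links_from_file(path: Union[str, Path]) -> list[str]:
    path = Path(path)
    raw = path.read_bytes()
    if b"\x00" in raw:
        raise HtmlParseError(f"binary content in saved page: {path}")
    try:
        return extract_supp_links(raw.decode("utf-8"))
    except UnicodeDecodeError:
        logger.info("falling back to latin-1 for %s", path)
        return extract_supp_links(raw.decode("latin-1"))
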