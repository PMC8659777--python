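"""Three-subblock circular buffer for streaming block processing.

The buffer divides its storage into three equal blocks: *historical* data
(already processed, kept as filter warm-up context), *current* data (ready
for processing) and *pending* data (being collected).  Two phases
alternate: samples accumulate in pending until it is full (push reports a
ready-signal), then :meth:`BlockBuffer.swap` rotates the roles — current
becomes historical, pending becomes current, and the old historical slot
is cleared to receive new samples.

Samples arriving between the ready-signal and the swap are staged in a
small FIFO and drained into pending after the swap, so nothing is ever
dropped: concatenating successive current blocks reproduces the input
stream exactly, with a constant memory footprint of three blocks.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator

import numpy as np

__all__ = ["BlockBuffer", "BufferStateError", "iter_blocks"]


class BufferStateError(RuntimeError):
    """Raised on an operation not valid in the buffer's current phase."""


class BlockBuffer:
    """Block circular buffer with historical / current / pending subblocks."""

    def __init__(self, block_size: int):
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        self.block_size = int(block_size)
        self._historical = np.empty(0)
        self._current = np.empty(0)
        self._pending: list[float] = []
        self._overflow: deque[float] = deque()
        self._ready = False
        self.swap_count = 0

    # -- state ------------------------------------------------------------

    @property
    def historical(self) -> np.ndarray:
        return self._historical

    @property
    def current(self) -> np.ndarray:
        return self._current

    @property
    def pending(self) -> np.ndarray:
        return np.asarray(self._pending, dtype=np.float64)

    @property
    def fill_count(self) -> int:
        return len(self._pending)

    @property
    def ready(self) -> bool:
        """True when pending holds a full block and a swap is due."""
        return self._ready

    # -- operations -------------------------------------------------------

    def push(self, sample: float) -> bool:
        """Append one sample; return True when a block swap is due.

        After the ready-signal and before :meth:`swap`, further samples go
        to an overflow staging FIFO (never dropped).
        """
        if self._ready:
            self._overflow.append(float(sample))
            return True
        self._pending.append(float(sample))
        if len(self._pending) == self.block_size:
            self._ready = True
        return self._ready

    def swap(self) -> tuple[np.ndarray, np.ndarray]:
        """Rotate block roles; return the (historical, current) window.

        current → historical, pending → current; the cleared slot becomes
        the new pending target and staged overflow samples are drained
        into it (which may immediately re-arm the ready-signal).
        """
        if not self._ready:
            raise BufferStateError("swap requested without a ready-signal")
        self._historical = self._current
        self._current = np.asarray(self._pending, dtype=np.float64)
        self._pending = []
        self._ready = False
        self.swap_count += 1
        while self._overflow and not self._ready:
            self.push(self._overflow.popleft())
        return self._historical, self._current


def iter_blocks(
    samples: Iterable[float], block_size: int
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream samples through a :class:`BlockBuffer`.

    Yields the (historical, current) processing window for every completed
    block, in order.  The trailing partial block is not yielded.
    """
    buf = BlockBuffer(block_size)
    for x in samples:
        if buf.push(x):
            yield buf.swap()
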