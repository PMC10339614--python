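"""NHS/CHI number validation and synthetic test-number generation.

NHS numbers (England/Wales/NI) and CHI numbers (Scotland) are 10-digit
identifiers whose final digit is a modulus-11 check digit over the first
nine digits, weighted 10 down to 2.  A remainder that would require a
check digit of 10 means no valid number exists with that 9-digit prefix.

Synthetic numbers produced here are drawn from the 999* range, which is
reserved and never allocated to real patients, so generated fixtures can
never collide with a live identifier.
"""

from __future__ import annotations

import numpy as np

_WEIGHTS = (10, 9, 8, 7, 6, 5, 4, 3, 2)

#: Prefix of the reserved, non-allocatable test range.
TEST_PREFIX = "999"


def canonicalise(identifier: str) -> str:
    """Strip the spaces and hyphens of the conventional 3-3-4 print layout."""
    return identifier.replace(" ", "").replace("-", "")


def check_digit(nine_digits: str) -> int | None:
    """Modulus-11 check digit for a 9-digit prefix, or None if none exists.

    check = 11 - (weighted sum mod 11), with 11 mapped to 0; a result of
    10 means the prefix admits no valid number.
    """
    if len(nine_digits) != 9 or not nine_digits.isdigit():
        raise ValueError(f"expected 9 digits, got {nine_digits!r}")
    total = sum(int(c) * w for c, w in zip(nine_digits, _WEIGHTS))
    check = 11 - (total % 11)
    if check == 11:
        return 0
    if check == 10:
        return None
    return check


def validate_nhs_number(identifier: object) -> bool:
    """True iff *identifier* canonicalises to 10 digits with a correct check digit.

    Any non-string or malformed input returns False; nothing raises.
    """
    if not isinstance(identifier, str):
        return False
    s = canonicalise(identifier)
    if len(s) != 10 or not s.isdigit():
        return False
    expected = check_digit(s[:9])
    return expected is not None and expected == int(s[9])


def generate_test_numbers(n: int, rng: np.random.Generator) -> list[str]:
    """Draw *n* distinct valid NHS-style numbers from the reserved 999* range."""
    numbers: list[str] = []
    seen: set[str] = set()
    while len(numbers) < n:
        body = "".join(str(d) for d in rng.integers(0, 10, size=6))
        prefix = TEST_PREFIX + body
        check = check_digit(prefix)
        if check is None:
            continue
        number = prefix + str(check)
        if number not in seen:
            seen.add(number)
            numbers.append(number)
    return numbers


def corrupt_identifier(identifier: str, rng: np.random.Generator,
                       position: int | None = None) -> str:
    """Substitute one digit of a 10-digit identifier with a different digit.

    Models mistyped identifiers in source study databases.  The result
    always differs from the input at exactly one position; because the
    check scheme's modulus is prime, a single substitution always breaks
    a previously valid check digit.
    """
    if not isinstance(identifier, str) or len(identifier) != 10 or not identifier.isdigit():
        raise ValueError(f"expected a 10-digit string, got {identifier!r}")
    pos = int(rng.integers(0, 10)) if position is None else position
    if not 0 <= pos < 10:
        raise ValueError(f"position out of range: {pos}")
    old = identifier[pos]
    alternatives = [d for d in "0123456789" if d != old]
    new = alternatives[int(rng.integers(0, 9))]
    return identifier[:pos] + new + identifier[pos + 1:]
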