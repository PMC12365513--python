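"""Independent brute-force references the fast implementations are checked against."""

import itertools
from typing import Dict, Tuple

from tirpscope.core import STIDatabase, UNRELATED, allen_relation


def exhaustive_frequent_patterns(
    db: STIDatabase,
    min_vs: int,
    max_gap: float,
    epsilon: float = 0.0,
) -> Dict[Tuple[tuple, tuple], Dict[str, int]]:
    """Enumerate every lexicographic STI subset of every transaction,
    derive its relation signature, and threshold distinct-transaction
    counts.  Returns {(symbols, relations): {txn_id: HS}}."""
    signatures: Dict[Tuple[tuple, tuple], Dict[str, int]] = {}
    for txn in db:
        stis = txn.stis
        local: Dict[Tuple[tuple, tuple], int] = {}
        for k in range(1, len(stis) + 1):
            for combo in itertools.combinations(range(len(stis)), k):
                rels = []
                valid = True
                for j in range(1, k):
                    for i in range(j):
                        rel = allen_relation(
                            stis[combo[i]], stis[combo[j]], epsilon, max_gap
                        )
                        if rel is UNRELATED:
                            valid = False
                            break
                        rels.append(rel)
                    if not valid:
                        break
                if not valid:
                    continue
                key = (tuple(stis[c].symbol for c in combo), tuple(rels))
                local[key] = local.get(key, 0) + 1
        for key, hs in local.items():
            signatures.setdefault(key, {})[txn.id] = hs
    return {
        key: supp for key, supp in signatures.items() if len(supp) >= min_vs
    }


def random_small_db(rng, max_txns=5, max_stis=12, max_symbols=5):
    """A random tiny database for exhaustive-oracle comparisons."""
    from tirpscope.core import STI, Transaction

    n_txn = int(rng.integers(1, max_txns + 1))
    alphabet = [chr(65 + i) for i in range(int(rng.integers(2, max_symbols + 1)))]
    txns = []
    for t in range(n_txn):
        stis = []
        for _ in range(int(rng.integers(0, max_stis + 1))):
            start = float(rng.integers(0, 20))
            stis.append(
                STI(
                    alphabet[int(rng.integers(len(alphabet)))],
                    start,
                    start + float(rng.integers(0, 6)),
                )
            )
        txns.append(Transaction(f"t{t}", tuple(stis)))
    return STIDatabase(txns, frozenset(alphabet))
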