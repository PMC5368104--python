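# molcontest

An evaluation toolkit for community contests in small-molecule
identification from tandem mass spectrometry (MS/MS). In such contests each
*challenge* is an MS/MS spectrum of a "known unknown": participants receive
a candidate list of plausible structures sharing the precursor's exact-mass
window and submit a non-negative score per candidate (higher = better). The
organizers then have to answer, automatically and reproducibly: *which
method ranked the correct structure best, challenge by challenge and
overall?*

`molcontest` implements that automated evaluation as a reusable library plus
a thin CLI:

- **Submission validation and I/O** — two-column tab-separated submission
  files (structure, score), candidate-list CSVs with configurable column
  dialects, solution tables.
- **Stereoisomer-collapsed, tie-averaged ranking.** MS/MS cannot distinguish
  stereoisomers, so candidates are collapsed on the first 14-character block
  of the InChIKey (the stereo-free "skeleton"), retaining the highest-scoring
  isomer. The rank of the correct candidate with `B` strictly better
  candidates and a tie of size `t` is the mean over all orderings of the
  tied block, `r = B + (t + 1)/2`; non-integer ranks are rounded **up**
  wherever an integer rank is needed (a two-way tie at the top is rank 1.5,
  counted as 2).
- **Contest statistics.** Per challenge, gold goes to the contestant(s) with
  the lowest rank (joint positions allowed; a winner exists even if nobody
  was Top 1); the overall winner follows the Olympic medal tally (gold, then
  silver, then bronze). Per entry: Top-1/3/10 counts split by ion mode,
  mean/median rank, relative ranking position `RRP = (TC − r)/(TC − 1)`,
  rank quantiles, the Formula 1 Score (25, 18, 15, 12, 10, 8, 6, 4, 2, 1
  points for ranks 1–10) and the Medal Score (5/3/1 points for ranks 1/2/3).
- **Consensus score fusion** — per-challenge max-normalization of
  heterogeneous scores, weighted sums over the union of candidates, and
  metadata scorers: literature reference counts, lowest database identifier,
  database presence (+10 per database), and a retention-time score from a
  linear hydrophobicity-descriptor→RT calibration.
- **Spectra** — plain-text and MGF peak lists, ppm-tolerant cosine
  similarity (normalized dot product, greedy peak matching), a spectral
  library-search baseline (precursor window, then cosine ranking), and the
  training/challenge dataset split (training iff best library similarity is
  strictly above 0.85, with an exception list).
- **A synthetic contest generator** so the whole pipeline is testable
  end-to-end without any external data: fake-but-valid InChIKeys with
  stereoisomer duplicates, Beta(α, 1) method-quality model, score ties,
  partial coverage, top-k truncation, heavy-tailed reference counts and a
  noisy linear RT model.

## Worked example

```python
from molcontest import CollapsedSubmission, rank_correct, formula1_score, medal_score

# three candidates after stereo collapse; the correct one ties at the top
sub = CollapsedSubmission("challenge-001", {"CORRECT": 10.0, "OTHER": 10.0, "THIRD": 1.0})
r = rank_correct(sub, "CORRECT")
print(r.average_rank, r.rounded_rank, round(r.rrp, 2))
print(formula1_score([r]), medal_score([r]))
```

prints

```
1.5 2 0.75
18 3
```

The correct candidate shares the top score with one other, so its
tie-averaged rank is 1.5, rounded up to 2 for integer-rank scoring: it
counts toward Top 3 but not Top 1, earns 18 Formula 1 points (rank-2 weight)
and 3 Medal Score points (silver). Its RRP is 0.75 on a 3-candidate list
(1 would be a unique best, 0 a unique worst).

A full synthetic contest, end to end:

```bash
molcontest simulate --seed 7 --n-challenges 50 --out-dir contest \
    --method strong:5.0 --method weak:1.0
molcontest evaluate --contest-dir contest --entries contest/submissions \
    --out-dir results
```

which writes `ranks.csv` (per-challenge tie-averaged ranks), `summary.csv`
(the statistic panel per entry), `medal_board.csv` and `standings.json`
(Olympic tally — `strong` wins). `molcontest matrix` exports the
log10-scaled rank matrix used for heat maps, with missing cells replaced by
the challenge's candidate count.

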