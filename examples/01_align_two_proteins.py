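"""Globally align two protein sequences and report EMBOSS-style statistics.

Percent similarity counts alignment columns whose residue pair scores
positively under BLOSUM62 (identities included) over the full alignment
length, gaps included — the per-pair number the conservation map is built
from.
"""

from orthoprofiler import GapPenalties, SubstitutionMatrix, needleman_wunsch
from orthoprofiler.alignment import format_alignment

human = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
fish = "MKTAYLAKQRSISFVKSHFARQLEERLGLVEVQTPILSRVGDGTQDNLSGSEKAIQ"

result = needleman_wunsch(human, fish, SubstitutionMatrix.load("BLOSUM62"),
                          GapPenalties(open=10.0, extend=0.5))
print(format_alignment(result, "human", "fish"))
print(f"identity   {result.pct_identity:5.1f}%  (identical residues / alignment length)")
print(f"similarity {result.pct_similarity:5.1f}%  (positively scoring pairs / alignment length)")
print(f"gaps       {result.pct_gaps:5.1f}%  (gap columns / alignment length)")
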