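# Bundled Sudoku puzzles, one per line: name then 81-char row-major clue
# string ('0' = blank).  sudoku-easy and sudoku-hard are synthetic stand-ins:
# representative puzzles of the stated difficulty tiers, used because the
# original clue grids could not be transcribed from the figure panels.
# ai-escargot is Arto Inkala's 2006 puzzle of that name.
sudoku-easy 003020600900305001001806400008102900700000008006708200002609500800203009005010300
sudoku-hard 800000000003600000070090200050007000000045700000100030001000068008500010090000400
ai-escargot 100007090030020008009600500005300900010080002600004000300000010040000007007000300
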