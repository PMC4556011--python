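# Connected approximation of the adjacency of Zimbabwe's 10 provinces.
# The two city provinces are attached to a single surrounding province:
# Harare -> Mashonaland East, Bulawayo -> Matabeleland North. Remaining
# edges follow shared land borders. Dialect: region count; then per region a
# label line, a neighbour-count line, and a line of 0-based neighbour
# indices. Region order fixes the index meaning throughout the package.
10
Bulawayo
1
7
Harare
1
4
Manicaland
2
4 6
Mashonaland Central
2
4 5
Mashonaland East
6
1 2 3 5 6 9
Mashonaland West
4
3 4 7 9
Masvingo
4
2 4 8 9
Matabeleland North
4
0 5 8 9
Matabeleland South
3
6 7 9
Midlands
5
4 5 6 7 8
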