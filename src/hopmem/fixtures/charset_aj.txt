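>A 12 8
00110100
01000011
11101011
11100101
10000011
11001110
11100111
01101011
01000110
11100011
11111011
01010010

>B 12 8
11111111
11100110
11000010
11000011
11110100
11101101
11100011
11000010
11000011
11001010
11100110
11111100

>C 12 8
00111100
01100010
11000000
11000001
11000001
11000100
11001010
11000001
10110100
11000010
00110010
00111110

>D 12 8
11110100
11100010
11000010
11000001
11110110
11101101
11100011
11000001
11000111
11001010
11110110
11111100

>E 12 8
11011011
11111101
11000010
11010010
11011100
10111100
01000010
11000100
11000011
11001010
11110100
11111100

>F 12 8
11001011
11111101
01000000
11000110
11111100
10111100
01000010
11010000
11000001
11001001
11110000
11111000

>G 12 8
00111100
01100010
11001011
11100001
11000001
11000100
11101111
11100011
10010010
11010010
01110010
01110110

>H 12 8
11001011
11111111
11000011
11010011
11111100
01111111
01100111
11000010
01000001
11101010
11100101
11010011

>I 12 8
01110111
00111100
00011000
00011100
00011000
00010000
00011010
00011000
10011100
00010100
01100110
00101100

>J 12 8
10110111
00111110
00011100
00010110
10100100
00000110
00010110
00010110
11010100
11010100
01100000
00111010

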