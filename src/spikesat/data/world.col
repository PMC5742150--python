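c World map 4-coloring instance.
c Best-effort reconstruction of the UN member land-border list;
c island states without land borders are isolated vertices.
c label 1 Canada
c label 2 USA
c label 3 Mexico
c label 4 Guatemala
c label 5 Belize
c label 6 Honduras
c label 7 El_Salvador
c label 8 Nicaragua
c label 9 Costa_Rica
c label 10 Panama
c label 11 Colombia
c label 12 Haiti
c label 13 Dominican_Republic
c label 14 Venezuela
c label 15 Ecuador
c label 16 Peru
c label 17 Brazil
c label 18 Guyana
c label 19 Suriname
c label 20 Bolivia
c label 21 Chile
c label 22 Paraguay
c label 23 Argentina
c label 24 Uruguay
c label 25 Portugal
c label 26 Spain
c label 27 France
c label 28 Andorra
c label 29 Belgium
c label 30 Luxembourg
c label 31 Germany
c label 32 Switzerland
c label 33 Italy
c label 34 Monaco
c label 35 Netherlands
c label 36 Denmark
c label 37 Poland
c label 38 Czechia
c label 39 Austria
c label 40 Liechtenstein
c label 41 Slovenia
c label 42 Hungary
c label 43 Slovakia
c label 44 San_Marino
c label 45 Croatia
c label 46 Serbia
c label 47 Bosnia_Herzegovina
c label 48 Montenegro
c label 49 Albania
c label 50 Romania
c label 51 Bulgaria
c label 52 North_Macedonia
c label 53 Greece
c label 54 Turkey
c label 55 Ukraine
c label 56 Moldova
c label 57 Belarus
c label 58 Lithuania
c label 59 Russia
c label 60 Latvia
c label 61 Estonia
c label 62 Finland
c label 63 Sweden
c label 64 Norway
c label 65 Ireland
c label 66 United_Kingdom
c label 67 Morocco
c label 68 Algeria
c label 69 Mauritania
c label 70 Tunisia
c label 71 Libya
c label 72 Niger
c label 73 Mali
c label 74 Egypt
c label 75 Sudan
c label 76 Chad
c label 77 Israel
c label 78 Central_African_Republic
c label 79 South_Sudan
c label 80 Ethiopia
c label 81 Eritrea
c label 82 Kenya
c label 83 Uganda
c label 84 DR_Congo
c label 85 Djibouti
c label 86 Somalia
c label 87 Tanzania
c label 88 Rwanda
c label 89 Burundi
c label 90 Zambia
c label 91 Malawi
c label 92 Mozambique
c label 93 Congo_Republic
c label 94 Angola
c label 95 Gabon
c label 96 Cameroon
c label 97 Equatorial_Guinea
c label 98 Nigeria
c label 99 Burkina_Faso
c label 100 Benin
c label 101 Togo
c label 102 Ghana
c label 103 Ivory_Coast
c label 104 Guinea
c label 105 Liberia
c label 106 Senegal
c label 107 Gambia
c label 108 Guinea_Bissau
c label 109 Sierra_Leone
c label 110 Namibia
c label 111 Zimbabwe
c label 112 Botswana
c label 113 South_Africa
c label 114 Eswatini
c label 115 Lesotho
c label 116 Georgia
c label 117 Armenia
c label 118 Azerbaijan
c label 119 Iran
c label 120 Iraq
c label 121 Syria
c label 122 Lebanon
c label 123 Jordan
c label 124 Saudi_Arabia
c label 125 Kuwait
c label 126 Qatar
c label 127 UAE
c label 128 Oman
c label 129 Yemen
c label 130 Turkmenistan
c label 131 Afghanistan
c label 132 Pakistan
c label 133 Kazakhstan
c label 134 Mongolia
c label 135 China
c label 136 North_Korea
c label 137 Uzbekistan
c label 138 Kyrgyzstan
c label 139 Tajikistan
c label 140 India
c label 141 Nepal
c label 142 Bhutan
c label 143 Myanmar
c label 144 Laos
c label 145 Vietnam
c label 146 Bangladesh
c label 147 Thailand
c label 148 Cambodia
c label 149 Malaysia
c label 150 Indonesia
c label 151 Brunei
c label 152 Papua_New_Guinea
c label 153 Timor_Leste
c label 154 South_Korea
c label 155 Iceland
c label 156 Malta
c label 157 Cyprus
c label 158 Cuba
c label 159 Jamaica
c label 160 Bahamas
c label 161 Barbados
c label 162 Trinidad_Tobago
c label 163 Grenada
c label 164 St_Lucia
c label 165 St_Vincent
c label 166 Antigua_Barbuda
c label 167 St_Kitts_Nevis
c label 168 Dominica
c label 169 Cape_Verde
c label 170 Sao_Tome_Principe
c label 171 Comoros
c label 172 Seychelles
c label 173 Mauritius
c label 174 Madagascar
c label 175 Maldives
c label 176 Sri_Lanka
c label 177 Japan
c label 178 Philippines
c label 179 Singapore
c label 180 Fiji
c label 181 Vanuatu
c label 182 Solomon_Islands
c label 183 Samoa
c label 184 Tonga
c label 185 Kiribati
c label 186 Tuvalu
c label 187 Nauru
c label 188 Palau
c label 189 Marshall_Islands
c label 190 Micronesia
c label 191 New_Zealand
c label 192 Australia
p edge 192 306
e 1 2
e 2 3
e 3 4
e 3 5
e 4 5
e 4 6
e 4 7
e 6 7
e 6 8
e 8 9
e 9 10
e 10 11
e 12 13
e 11 14
e 11 15
e 11 16
e 11 17
e 14 18
e 14 17
e 18 19
e 18 17
e 19 17
e 15 16
e 16 17
e 16 20
e 16 21
e 20 17
e 20 21
e 20 22
e 20 23
e 22 17
e 22 23
e 17 23
e 17 24
e 23 24
e 23 21
e 25 26
e 26 27
e 26 28
e 27 28
e 27 29
e 27 30
e 27 31
e 27 32
e 27 33
e 27 34
e 29 35
e 29 30
e 29 31
e 35 31
e 30 31
e 31 36
e 31 37
e 31 38
e 31 39
e 31 32
e 32 33
e 32 39
e 32 40
e 39 40
e 39 33
e 39 41
e 39 42
e 39 43
e 39 38
e 33 41
e 33 44
e 41 45
e 41 42
e 45 42
e 45 46
e 45 47
e 45 48
e 47 46
e 47 48
e 48 46
e 48 49
e 46 42
e 46 50
e 46 51
e 46 52
e 49 53
e 49 52
e 52 53
e 52 51
e 53 51
e 53 54
e 51 50
e 51 54
e 50 42
e 50 55
e 50 56
e 56 55
e 42 43
e 42 55
e 43 38
e 43 37
e 43 55
e 37 38
e 37 55
e 37 57
e 37 58
e 37 59
e 58 60
e 58 57
e 58 59
e 60 61
e 60 59
e 60 57
e 61 59
e 57 59
e 57 55
e 55 59
e 62 63
e 62 64
e 62 59
e 63 64
e 64 59
e 65 66
e 67 68
e 67 69
e 68 70
e 68 71
e 68 72
e 68 73
e 68 69
e 70 71
e 71 74
e 71 75
e 71 76
e 71 72
e 74 75
e 74 77
e 75 76
e 75 78
e 75 79
e 75 80
e 75 81
e 79 80
e 79 82
e 79 83
e 79 84
e 79 78
e 81 80
e 81 85
e 80 85
e 80 86
e 80 82
e 85 86
e 86 82
e 82 83
e 82 87
e 83 87
e 83 88
e 83 84
e 88 87
e 88 89
e 88 84
e 89 87
e 89 84
e 87 90
e 87 91
e 87 92
e 84 93
e 84 78
e 84 94
e 84 90
e 93 95
e 93 96
e 93 78
e 93 94
e 95 96
e 95 97
e 96 97
e 96 98
e 96 76
e 96 78
e 76 72
e 76 98
e 76 78
e 72 98
e 72 73
e 72 99
e 72 100
e 98 100
e 100 101
e 100 99
e 101 102
e 101 99
e 102 99
e 102 103
e 99 73
e 99 103
e 103 73
e 103 104
e 103 105
e 73 69
e 73 106
e 73 104
e 69 106
e 106 107
e 106 108
e 106 104
e 108 104
e 104 105
e 104 109
e 109 105
e 94 90
e 94 110
e 90 91
e 90 92
e 90 111
e 90 112
e 90 110
e 91 92
e 92 111
e 92 113
e 92 114
e 111 112
e 111 113
e 112 110
e 112 113
e 110 113
e 113 115
e 113 114
e 54 116
e 54 117
e 54 118
e 54 119
e 54 120
e 54 121
e 121 122
e 121 77
e 121 123
e 121 120
e 122 77
e 77 123
e 123 120
e 123 124
e 120 119
e 120 125
e 120 124
e 125 124
e 124 126
e 124 127
e 124 128
e 124 129
e 127 128
e 128 129
e 119 117
e 119 118
e 119 130
e 119 131
e 119 132
e 116 59
e 116 117
e 116 118
e 117 118
e 118 59
e 59 133
e 59 134
e 59 135
e 59 136
e 133 137
e 133 130
e 133 138
e 133 135
e 137 130
e 137 138
e 137 139
e 137 131
e 130 131
e 138 139
e 138 135
e 139 131
e 139 135
e 131 132
e 131 135
e 132 135
e 132 140
e 135 140
e 135 141
e 135 142
e 135 134
e 135 143
e 135 144
e 135 145
e 135 136
e 140 141
e 140 142
e 140 146
e 140 143
e 146 143
e 143 147
e 143 144
e 147 144
e 147 148
e 147 149
e 144 145
e 144 148
e 148 145
e 149 150
e 149 151
e 150 152
e 150 153
e 136 154
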