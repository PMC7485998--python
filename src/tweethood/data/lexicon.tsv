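phrase	category	team_sport
kale	healthy_food	0
kale salad	healthy_food	0
collard greens	healthy_food	0
spinach	healthy_food	0
broccoli	healthy_food	0
green beans	healthy_food	0
beans	healthy_food	0
brown rice	healthy_food	0
quinoa	healthy_food	0
avocado	healthy_food	0
blueberries	healthy_food	0
strawberries	healthy_food	0
banana	healthy_food	0
apple	healthy_food	0
almonds	healthy_food	0
walnuts	healthy_food	0
grilled chicken	healthy_food	0
salmon	healthy_food	0
tofu	healthy_food	0
lentils	healthy_food	0
hummus	healthy_food	0
oatmeal	healthy_food	0
greek yogurt	healthy_food	0
sweet potato	healthy_food	0
cauliflower	healthy_food	0
asparagus	healthy_food	0
turkey	healthy_food	0
tomatoes	healthy_food	0
tomato	healthy_food	0
cucumber	healthy_food	0
carrots	healthy_food	0
salad	healthy_food	0
smoothie	healthy_food	0
roast beef	healthy_food	0
mcdonalds	fast_food	0
mcdonald's	fast_food	0
burger king	fast_food	0
taco bell	fast_food	0
kfc	fast_food	0
wendys	fast_food	0
chipotle	fast_food	0
pizzahut	fast_food	0
pizza hut	fast_food	0
starbucks	fast_food	0
dominos	fast_food	0
five guys	fast_food	0
dunkin	fast_food	0
popeyes	fast_food	0
chick fil a	fast_food	0
sonic drive in	fast_food	0
arbys	fast_food	0
fries	fast_food	0
cheeseburger	fast_food	0
big mac	fast_food	0
whopper	fast_food	0
mcnuggets	fast_food	0
frappuccino	fast_food	0
pizza	other_food	0
burger	other_food	0
sandwich	other_food	0
pasta	other_food	0
cake	other_food	0
ice cream	other_food	0
donut	other_food	0
coffee	other_food	0
tacos	other_food	0
sushi	other_food	0
bacon	other_food	0
chocolate	other_food	0
cookies	other_food	0
steak	other_food	0
ramen	other_food	0
noodles	other_food	0
wings	other_food	0
pancakes	other_food	0
waffles	other_food	0
brunch	other_food	0
workout	physical_activity	0
working out	physical_activity	0
gym	physical_activity	0
running	physical_activity	0
run	physical_activity	0
jog	physical_activity	0
jogging	physical_activity	0
hike	physical_activity	0
hiked	physical_activity	0
hiking	physical_activity	0
yoga	physical_activity	0
pilates	physical_activity	0
swim	physical_activity	0
swimming	physical_activity	0
bike ride	physical_activity	0
biking	physical_activity	0
cycling	physical_activity	0
lifting weights	physical_activity	0
weightlifting	physical_activity	0
crossfit	physical_activity	0
zumba	physical_activity	0
treadmill	physical_activity	0
elliptical	physical_activity	0
squats	physical_activity	0
deadlift	physical_activity	0
push ups	physical_activity	0
pull ups	physical_activity	0
marathon	physical_activity	0
sprints	physical_activity	0
skating	physical_activity	0
skiing	physical_activity	0
snowboarding	physical_activity	0
surfing	physical_activity	0
climbing	physical_activity	0
rowing	physical_activity	0
walk	physical_activity	0
walking	physical_activity	0
dance class	physical_activity	0
spin class	physical_activity	0
stretching	physical_activity	0
cardio	physical_activity	0
basketball	physical_activity	1
soccer	physical_activity	1
football	physical_activity	1
baseball	physical_activity	1
volleyball	physical_activity	1
hockey	physical_activity	1
softball	physical_activity	1
lacrosse	physical_activity	1
rugby	physical_activity	1
kickball	physical_activity	1
dodgeball	physical_activity	1
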